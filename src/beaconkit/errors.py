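"""Typed error hierarchy shared across the package.

Protocol-level refusals (consent denial, budget exhaustion) are represented as
response markers, not exceptions; exceptions here signal contract violations or
unusable inputs.
"""


class BeaconKitError(Exception):
    """Base class for all package errors."""


class UnsupportedAlleleError(BeaconKitError):
    """Allele contains characters outside [ACGT] (symbolic ALT, breakend, N...)."""


class DegenerateAlleleError(BeaconKitError):
    """Reference and alternate alleles are identical after normalization."""


class AssemblyMismatchError(BeaconKitError):
    """Query key and dataset index were built against different assemblies."""


class IngestError(BeaconKitError):
    """A VCF could not be read or parsed."""


class AuthenticationError(BeaconKitError):
    """Credential token is present but unknown to the token registry."""


class UnknownDatasetError(BeaconKitError):
    """A query named a dataset_id the beacon does not serve."""


class RegistrationError(BeaconKitError):
    """A beacon could not be added to a network registry."""


class DomainError(BeaconKitError):
    """A numeric argument is outside its mathematical domain."""


class ConfigError(BeaconKitError):
    """A service/scenario configuration file is invalid."""
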