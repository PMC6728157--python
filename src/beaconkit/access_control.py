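"""Access tiers, progressive-disclosure redaction, and consent-code gating.

Beacons expose three ordered access tiers — open, registered, controlled —
with strictly more response metadata unlocked at each tier (progressive
disclosure).  Datasets additionally carry a Consent Code describing what
research uses their participants consented to; a query's declared research
purpose is matched against that code before any lookup happens.

Tokens are an intentionally simple stand-in for institutional authentication:
a registry maps opaque token strings to tiers, and an absent token always
resolves to the open tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import TYPE_CHECKING, FrozenSet, Mapping, Optional, Tuple

from .errors import AuthenticationError

if TYPE_CHECKING:  # pragma: no cover
    from .beacon_core import AlleleResponse


class AccessTier(IntEnum):
    """Ordered disclosure levels: OPEN < REGISTERED < CONTROLLED."""

    OPEN = 0
    REGISTERED = 1
    CONTROLLED = 2

    @classmethod
    def parse(cls, value) -> "AccessTier":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return cls(value)
        return cls[str(value).upper()]


ANONYMOUS_POOL_KEY = "anonymous-open-pool"


@dataclass(frozen=True, slots=True)
class Credential:
    """A caller's identity for tier resolution and budget accounting.

    An absent token means an anonymous caller; all anonymous callers share one
    budget identity (the open pool), since they cannot be told apart.
    ``tier_claim`` caps the tier the token may grant.
    """

    token: Optional[str] = None
    tier_claim: AccessTier = AccessTier.CONTROLLED
    identity_key: str = ""

    def __post_init__(self):
        if not self.identity_key:
            object.__setattr__(
                self, "identity_key", self.token if self.token else ANONYMOUS_POOL_KEY
            )

    @classmethod
    def anonymous(cls) -> "Credential":
        return cls(token=None)


def resolve_tier(
    credential: Credential, token_registry: Mapping[str, AccessTier]
) -> AccessTier:
    """Map a credential to its access tier.

    No token resolves to OPEN.  A known token resolves to its registered tier,
    capped by the credential's own claim (resolution never escalates).  An
    unknown token is an authentication error, never a silent downgrade to OPEN.
    """
    if credential.token is None:
        return AccessTier.OPEN
    if credential.token not in token_registry:
        raise AuthenticationError(f"unknown token {credential.token!r}")
    registered = AccessTier.parse(token_registry[credential.token])
    return min(registered, credential.tier_claim)


# ---------------------------------------------------------------------------
# Consent Codes
# ---------------------------------------------------------------------------


class ConsentCategory(str, Enum):
    """Primary data-use categories of the Consent Codes scheme."""

    NRES = "NRES"  # no restriction
    GRU = "GRU"  # general research use
    HMB = "HMB"  # health/medical/biomedical research
    DS = "DS"  # disease-specific research
    POA = "POA"  # population origins/ancestry research only


class PurposeCategory(str, Enum):
    general_research = "general_research"
    health_medical_biomedical = "health_medical_biomedical"
    disease_specific = "disease_specific"
    population_origins = "population_origins"


@dataclass(frozen=True, slots=True)
class ConsentCode:
    """A dataset's consent-based data-use condition.

    ``disease_term`` is required exactly when the primary category is DS.
    Secondary modifiers are carried for display but not enforced; their
    semantics need policy context a software artifact cannot verify.
    """

    primary_category: ConsentCategory
    disease_term: Optional[str] = None
    secondary_requirements: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.primary_category is ConsentCategory.DS and not self.disease_term:
            raise ValueError("DS consent requires a nonempty disease_term")


@dataclass(frozen=True, slots=True)
class ResearchPurpose:
    """A query's declared research purpose."""

    category: PurposeCategory = PurposeCategory.general_research
    disease_term: Optional[str] = None

    def __post_init__(self):
        if self.category is PurposeCategory.disease_specific and not self.disease_term:
            raise ValueError("disease_specific purpose requires a disease_term")


@dataclass(frozen=True, slots=True)
class ConsentDecision:
    allowed: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.allowed


_ALLOW = ConsentDecision(True)


def check_consent(consent_code: ConsentCode, purpose: ResearchPurpose) -> ConsentDecision:
    """Evaluate the consent decision table; total over all (code, purpose) pairs.

    NRES allows everything; GRU allows all research categories; HMB allows
    health/medical/biomedical and disease-specific research; DS(t) allows only
    disease-specific research with an exact term match on t; POA allows only
    population-origins research.
    """
    cat = consent_code.primary_category
    p = purpose.category
    if cat in (ConsentCategory.NRES, ConsentCategory.GRU):
        return _ALLOW
    if cat is ConsentCategory.HMB:
        if p in (
            PurposeCategory.health_medical_biomedical,
            PurposeCategory.disease_specific,
        ):
            return _ALLOW
        return ConsentDecision(False, f"HMB consent does not cover purpose {p.value}")
    if cat is ConsentCategory.DS:
        if p is PurposeCategory.disease_specific and (
            purpose.disease_term == consent_code.disease_term
        ):
            return _ALLOW
        return ConsentDecision(
            False,
            f"DS({consent_code.disease_term}) consent does not cover this purpose",
        )
    if cat is ConsentCategory.POA:
        if p is PurposeCategory.population_origins:
            return _ALLOW
        return ConsentDecision(False, f"POA consent does not cover purpose {p.value}")
    raise AssertionError(f"unhandled consent category {cat!r}")  # unreachable


# ---------------------------------------------------------------------------
# Progressive-disclosure redaction
# ---------------------------------------------------------------------------

#: Optional DatasetAlleleResponse fields unlocked at each tier. The sets form a
#: superset chain, which is what makes disclosure "progressive". The mapping is
#: a policy default and can be overridden per beacon.
DEFAULT_TIER_FIELDS: Mapping[AccessTier, FrozenSet[str]] = {
    AccessTier.OPEN: frozenset(),
    AccessTier.REGISTERED: frozenset({"frequency", "allele_count"}),
    AccessTier.CONTROLLED: frozenset(
        {"frequency", "allele_count", "sample_count", "extra_metadata"}
    ),
}

_REDACTABLE = ("frequency", "allele_count", "sample_count", "extra_metadata")


def redact(
    response: "AlleleResponse",
    tier: AccessTier,
    tier_fields: Mapping[AccessTier, FrozenSet[str]] = DEFAULT_TIER_FIELDS,
) -> "AlleleResponse":
    """Strip per-dataset metadata the caller's tier does not unlock (in place).

    The existence bit and any denial note survive every tier; everything else
    is cleared unless listed in ``tier_fields[tier]``.
    """
    allowed = tier_fields[tier]
    for ds in response.dataset_responses:
        for name in _REDACTABLE:
            if name not in allowed:
                setattr(ds, name, None)
    return response
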