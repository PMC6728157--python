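"""The beacon protocol engine.

A beacon exposes exactly two functions: ``info`` describes the host and the
datasets it serves, and ``query`` answers whether an allele has been observed,
"yes" or "no".  The query path runs, per selected dataset: consent gate ->
budget gate -> exact-match lookup; the beacon-level answer is the OR over the
datasets that passed both gates.  Gated-out datasets are reported as denied —
never as a false "no", which would corrupt any federation-level aggregation —
and carry no existence bit at all.

The wire dialect (GET / and GET /query with camelCase parameters) lives at the
bottom of this module as pure request-handler functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from . import access_control as ac
from . import allele_store as store
from . import privacy_budget as pb
from .errors import (
    AssemblyMismatchError,
    AuthenticationError,
    DegenerateAlleleError,
    UnsupportedAlleleError,
)

logger = logging.getLogger(__name__)

API_VERSION = "1.0.0"


@dataclass(slots=True)
class DatasetInfo:
    dataset_id: str
    name: str
    description: str
    assembly_id: str
    variant_count: int
    sample_count: Optional[int]
    consent_code: ac.ConsentCode
    minimum_tier: ac.AccessTier

    def to_dict(self) -> dict:
        return {
            "id": self.dataset_id,
            "name": self.name,
            "description": self.description,
            "assemblyId": self.assembly_id,
            "variantCount": self.variant_count,
            "sampleCount": self.sample_count,
            "consentCode": {
                "primaryCategory": self.consent_code.primary_category.value,
                "diseaseTerm": self.consent_code.disease_term,
                "secondaryRequirements": list(self.consent_code.secondary_requirements),
            },
            "minimumTier": self.minimum_tier.name,
        }


@dataclass(slots=True)
class BeaconInfo:
    beacon_id: str
    organization: str
    description: str
    api_version: str = API_VERSION
    datasets: List[DatasetInfo] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "id": self.beacon_id,
            "organization": self.organization,
            "description": self.description,
            "apiVersion": self.api_version,
            "datasets": [d.to_dict() for d in self.datasets],
        }


@dataclass(slots=True)
class AlleleQuery:
    """An allele-presence question. ``start`` is 0-based."""

    assembly_id: str
    chromosome: str
    start: int
    ref_bases: str
    alt_bases: str
    dataset_ids: Optional[Sequence[str]] = None
    purpose: ac.ResearchPurpose = field(default_factory=ac.ResearchPurpose)
    include_dataset_responses: bool = False


@dataclass(slots=True)
class DatasetAlleleResponse:
    """Per-dataset verdict. ``exists`` is None when the dataset was gated out;
    ``note`` then says why (the refusal carries no existence information)."""

    dataset_id: str
    exists: Optional[bool]
    frequency: Optional[float] = None
    allele_count: Optional[int] = None
    sample_count: Optional[int] = None
    extra_metadata: Optional[Dict[str, str]] = None
    note: Optional[str] = None

    def to_dict(self) -> dict:
        out: dict = {"datasetId": self.dataset_id, "exists": self.exists}
        if self.frequency is not None:
            out["frequency"] = self.frequency
        if self.allele_count is not None:
            out["alleleCount"] = self.allele_count
        if self.sample_count is not None:
            out["sampleCount"] = self.sample_count
        if self.extra_metadata:
            out["info"] = dict(self.extra_metadata)
        if self.note is not None:
            out["note"] = self.note
        return out


@dataclass(slots=True)
class BeaconProtocolError:
    code: str
    message: str

    def to_dict(self) -> dict:
        return {"errorCode": self.code, "message": self.message}


@dataclass(slots=True)
class AlleleResponse:
    """The beacon's reply: a yes/no bit, optional per-dataset detail, or a
    typed error/refusal. ``exists`` and ``error`` are never both set; a fully
    refused query has ``exists is None``."""

    beacon_id: str
    exists: Optional[bool]
    dataset_responses: List[DatasetAlleleResponse] = field(default_factory=list)
    error: Optional[BeaconProtocolError] = None

    def to_dict(self) -> dict:
        out: dict = {"beaconId": self.beacon_id, "exists": self.exists}
        if self.dataset_responses:
            out["datasetAlleleResponses"] = [d.to_dict() for d in self.dataset_responses]
        if self.error is not None:
            out["error"] = self.error.to_dict()
        return out


@dataclass(slots=True)
class _Dataset:
    index: store.DatasetIndex
    consent_code: ac.ConsentCode
    minimum_tier: ac.AccessTier
    name: str
    description: str


class Beacon:
    """One beacon serving zero or more VCF-derived dataset indexes."""

    def __init__(
        self,
        beacon_id: str,
        organization: str = "",
        description: str = "",
        token_registry: Optional[Mapping[str, ac.AccessTier]] = None,
        ledger: Optional[pb.BudgetLedger] = None,
        cost_policy: Optional[pb.CostPolicy] = None,
        tier_fields: Mapping[ac.AccessTier, frozenset] = ac.DEFAULT_TIER_FIELDS,
    ):
        if not beacon_id:
            raise ValueError("beacon_id must be nonempty")
        self.beacon_id = beacon_id
        self.organization = organization
        self.description = description
        self.token_registry = dict(token_registry or {})
        self.ledger = ledger
        self.cost_policy = cost_policy or pb.CostPolicy()
        self.tier_fields = tier_fields
        self._datasets: Dict[str, _Dataset] = {}

    def add_dataset(
        self,
        index: store.DatasetIndex,
        consent_code: Optional[ac.ConsentCode] = None,
        minimum_tier: ac.AccessTier = ac.AccessTier.OPEN,
        name: str = "",
        description: str = "",
    ) -> "Beacon":
        if index.dataset_id in self._datasets:
            raise ValueError(f"duplicate dataset_id {index.dataset_id!r}")
        self._datasets[index.dataset_id] = _Dataset(
            index=index,
            consent_code=consent_code or ac.ConsentCode(ac.ConsentCategory.NRES),
            minimum_tier=minimum_tier,
            name=name or index.dataset_id,
            description=description,
        )
        return self

    @property
    def dataset_ids(self) -> List[str]:
        return list(self._datasets)

    # -- the two protocol functions ------------------------------------------

    def info(self) -> BeaconInfo:
        """Describe the beacon and its datasets; counts echo the live indexes."""
        return BeaconInfo(
            beacon_id=self.beacon_id,
            organization=self.organization,
            description=self.description,
            datasets=[
                DatasetInfo(
                    dataset_id=ds.index.dataset_id,
                    name=ds.name,
                    description=ds.description,
                    assembly_id=ds.index.assembly_id,
                    variant_count=ds.index.record_count,
                    sample_count=ds.index.sample_total,
                    consent_code=ds.consent_code,
                    minimum_tier=ds.minimum_tier,
                )
                for ds in self._datasets.values()
            ],
        )

    def query(
        self, allele_query: AlleleQuery, credential: Optional[ac.Credential] = None
    ) -> AlleleResponse:
        """Answer an allele-presence query under the caller's tier and budget."""
        credential = credential or ac.Credential.anonymous()

        def _error(code: str, message: str) -> AlleleResponse:
            return AlleleResponse(
                beacon_id=self.beacon_id,
                exists=None,
                error=BeaconProtocolError(code, message),
            )

        try:
            tier = ac.resolve_tier(credential, self.token_registry)
        except AuthenticationError as exc:
            return _error("unauthenticated", str(exc))

        try:
            key = store.normalize_allele(
                allele_query.chromosome,
                allele_query.start + 1,  # public API is 0-based
                allele_query.ref_bases,
                allele_query.alt_bases,
                allele_query.assembly_id,
            )
        except (UnsupportedAlleleError, DegenerateAlleleError, ValueError) as exc:
            return _error("malformed_allele", str(exc))

        if self.ledger is not None and self.ledger.is_locked(credential.identity_key):
            return _error(
                "budget_exhausted",
                "information budget exhausted for this credential",
            )

        if allele_query.dataset_ids is not None:
            unknown = [d for d in allele_query.dataset_ids if d not in self._datasets]
            if unknown:
                return _error("unknown_dataset", f"unknown dataset id(s): {unknown}")
            selected = [self._datasets[d] for d in allele_query.dataset_ids]
        else:
            # default selection: every dataset the caller's tier can see
            selected = [
                ds for ds in self._datasets.values() if ds.minimum_tier <= tier
            ]

        dataset_responses: List[DatasetAlleleResponse] = []
        for ds in selected:
            did = ds.index.dataset_id
            if ds.minimum_tier > tier:
                dataset_responses.append(
                    DatasetAlleleResponse(did, None, note="denied: tier too low")
                )
                continue
            decision = ac.check_consent(ds.consent_code, allele_query.purpose)
            if not decision:
                dataset_responses.append(
                    DatasetAlleleResponse(
                        did,
                        None,
                        note=f"not authorized for this purpose: {decision.reason}",
                    )
                )
                continue
            try:
                record = store.lookup(ds.index, key)
            except AssemblyMismatchError as exc:
                dataset_responses.append(
                    DatasetAlleleResponse(did, None, note=f"assembly mismatch: {exc}")
                )
                continue
            exists = record is not None
            frequency = store.allele_frequency(record) if record else None
            if self.ledger is not None:
                cost = pb.query_cost(frequency, exists, self.cost_policy)
                if not self.ledger.charge_and_gate(credential.identity_key, cost):
                    # locked by an earlier dataset within this same query
                    dataset_responses.append(
                        DatasetAlleleResponse(
                            did, None, note="denied: information budget exhausted"
                        )
                    )
                    continue
            dataset_responses.append(
                DatasetAlleleResponse(
                    dataset_id=did,
                    exists=exists,
                    frequency=frequency,
                    allele_count=record.allele_count if record else None,
                    sample_count=record.sample_count if record else None,
                    extra_metadata=dict(record.extra_metadata) if record else None,
                )
            )

        answered = [d.exists for d in dataset_responses if d.exists is not None]
        exists: Optional[bool] = any(answered) if answered else None
        response = AlleleResponse(
            beacon_id=self.beacon_id,
            exists=exists,
            dataset_responses=dataset_responses,
        )
        if exists is None and dataset_responses:
            response.error = BeaconProtocolError(
                "all_datasets_denied", "no selected dataset was authorized to answer"
            )
        elif exists is None:
            # zero datasets selected/served: a valid "no information" reply
            response.exists = False
        response = ac.redact(response, tier, self.tier_fields)
        if not allele_query.include_dataset_responses:
            response.dataset_responses = []
        return response


# ---------------------------------------------------------------------------
# Wire dialect: pure handlers for the two HTTP routes.
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}


def handle_info_request(beacon: Beacon) -> tuple:
    """GET /  -> (status, JSON-serializable payload)."""
    return 200, beacon.info().to_dict()


def handle_query_request(
    beacon: Beacon, params: Mapping[str, str], token: Optional[str] = None
) -> tuple:
    """GET /query -> (status, payload).

    Recognized parameters: assemblyId, referenceName, start (0-based),
    referenceBases, alternateBases, datasetIds (comma-separated),
    includeDatasetResponses, purpose, diseaseTerm.
    """
    required = ("assemblyId", "referenceName", "start", "referenceBases", "alternateBases")
    missing = [k for k in required if not params.get(k)]
    if missing:
        return 400, {
            "error": {
                "errorCode": "missing_parameter",
                "message": f"missing required parameter(s): {missing}",
            }
        }
    try:
        start = int(params["start"])
    except ValueError:
        return 400, {
            "error": {"errorCode": "malformed_allele", "message": "start must be an integer"}
        }
    try:
        purpose = ac.ResearchPurpose(
            category=ac.PurposeCategory(params.get("purpose", "general_research")),
            disease_term=params.get("diseaseTerm"),
        )
    except ValueError as exc:
        return 400, {"error": {"errorCode": "bad_purpose", "message": str(exc)}}
    dataset_ids = None
    if params.get("datasetIds"):
        dataset_ids = [d for d in params["datasetIds"].split(",") if d]
    query = AlleleQuery(
        assembly_id=params["assemblyId"],
        chromosome=params["referenceName"],
        start=start,
        ref_bases=params["referenceBases"],
        alt_bases=params["alternateBases"],
        dataset_ids=dataset_ids,
        purpose=purpose,
        include_dataset_responses=params.get("includeDatasetResponses", "").lower()
        in _TRUE,
    )
    response = beacon.query(query, ac.Credential(token=token) if token else None)
    status = 200
    if response.error is not None:
        status = {
            "unauthenticated": 401,
            "budget_exhausted": 429,
            "unknown_dataset": 404,
            "malformed_allele": 400,
            "all_datasets_denied": 403,
        }.get(response.error.code, 400)
    return status, response.to_dict()
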