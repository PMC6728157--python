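"""Beacon federation: registry, fan-out, aggregation, origin-obscuring beacons.

A network turns "have you observed this allele?" into "who has observed this
allele?": one query fans out to every registered beacon, per-beacon outcomes
are recorded independently (one beacon failing or timing out never aborts the
rest, and unavailability is never conflated with a "no"), and the reply
carries the yes/no/error tallies.

An :class:`AggregateBeacon` is the opposite construction: several beacons are
fused behind a single front whose answer is the OR over its members while its
public face never names them, so an attacker cannot tell which member holds an
observed allele.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor, TimeoutError as FutureTimeout
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence

from .access_control import Credential
from .beacon_core import (
    AlleleQuery,
    AlleleResponse,
    BeaconInfo,
    BeaconProtocolError,
)
from .errors import RegistrationError

logger = logging.getLogger(__name__)

DEFAULT_TIMEOUT_S = 5.0


class BeaconHandle(Protocol):
    """Anything queryable as a beacon: in-process, aggregate, or HTTP client."""

    def info(self) -> BeaconInfo: ...

    def query(
        self, allele_query: AlleleQuery, credential: Optional[Credential] = None
    ) -> AlleleResponse: ...


@dataclass(slots=True)
class RegistryEntry:
    beacon_id: str
    handle: BeaconHandle
    organization: str = ""


class BeaconRegistry:
    """Directory of beacons addressable by the network."""

    def __init__(self):
        self.entries: Dict[str, RegistryEntry] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def register(self, handle: BeaconHandle, organization: str = "") -> "BeaconRegistry":
        """Add a beacon after probing its info(); duplicates are rejected."""
        try:
            info = handle.info()
        except Exception as exc:
            raise RegistrationError(f"beacon unreachable at registration: {exc}") from exc
        if info.beacon_id in self.entries:
            raise RegistrationError(f"duplicate beacon id {info.beacon_id!r}")
        self.entries[info.beacon_id] = RegistryEntry(
            beacon_id=info.beacon_id,
            handle=handle,
            organization=organization or info.organization,
        )
        return self

    def directory(self) -> List[dict]:
        return [
            {"beaconId": e.beacon_id, "organization": e.organization}
            for e in self.entries.values()
        ]


@dataclass(slots=True)
class NetworkResponse:
    """Aggregated fan-out outcome.

    ``per_beacon`` maps each queried beacon to its response or, on transport
    failure/timeout, to a failure marker.  ``yes_count`` counts beacons that
    answered True, ``no_count`` those that answered False, ``error_count``
    everything else (failures, refusals, protocol errors) — the three tallies
    partition the queried beacons.
    """

    query: dict
    per_beacon: Dict[str, AlleleResponse] = field(default_factory=dict)
    yes_count: int = 0
    no_count: int = 0
    error_count: int = 0

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "yesCount": self.yes_count,
            "noCount": self.no_count,
            "errorCount": self.error_count,
            "responses": {bid: r.to_dict() for bid, r in self.per_beacon.items()},
        }


def _query_echo(q: AlleleQuery) -> dict:
    return {
        "assemblyId": q.assembly_id,
        "referenceName": q.chromosome,
        "start": q.start,
        "referenceBases": q.ref_bases,
        "alternateBases": q.alt_bases,
    }


def federated_query(
    registry: BeaconRegistry,
    allele_query: AlleleQuery,
    credential: Optional[Credential] = None,
    timeout: float = DEFAULT_TIMEOUT_S,
) -> NetworkResponse:
    """Fan one query out to every registered beacon and tally the answers.

    The caller's credential is forwarded unchanged; each beacon applies its own
    tier/consent/budget policy locally.  Fan-out is concurrent with a
    per-beacon timeout; a timeout or exception is recorded as a failure marker
    for that beacon only.
    """
    response = NetworkResponse(query=_query_echo(allele_query))
    if not registry.entries:
        response.error_count = 0
        response.query["note"] = "no beacons registered"
        return response
    entries = list(registry.entries.values())
    with ThreadPoolExecutor(max_workers=min(8, len(entries))) as pool:
        futures = {
            e.beacon_id: pool.submit(e.handle.query, allele_query, credential)
            for e in entries
        }
        for beacon_id, future in futures.items():
            try:
                result = future.result(timeout=timeout)
            except FutureTimeout:
                result = AlleleResponse(
                    beacon_id=beacon_id,
                    exists=None,
                    error=BeaconProtocolError("timeout", f"no answer within {timeout}s"),
                )
            except Exception as exc:  # fault isolation: never abort the fan-out
                logger.warning("beacon %s failed: %s", beacon_id, exc)
                result = AlleleResponse(
                    beacon_id=beacon_id,
                    exists=None,
                    error=BeaconProtocolError("beacon_failure", str(exc)),
                )
            response.per_beacon[beacon_id] = result
            if result.exists is True:
                response.yes_count += 1
            elif result.exists is False:
                response.no_count += 1
            else:
                response.error_count += 1
    return response


class AggregateBeacon:
    """A beacon fused from hidden members; answers the OR over their answers.

    Member queries are forwarded live (no merged index), so members keep
    autonomy over their own data and policies.  ``info()`` and every response
    expose only the aggregate's own identity — never a member's.
    """

    def __init__(
        self,
        beacon_handles: Sequence[BeaconHandle],
        aggregate_id: str,
        organization: str = "",
        description: str = "an aggregate beacon; member identities are not disclosed",
    ):
        if not beacon_handles:
            raise ValueError("an aggregate beacon needs at least one member")
        self.beacon_id = aggregate_id
        self.organization = organization
        self.description = description
        self._members = list(beacon_handles)

    def info(self) -> BeaconInfo:
        return BeaconInfo(
            beacon_id=self.beacon_id,
            organization=self.organization,
            description=self.description,
            datasets=[],  # enumerating member datasets would leak member identity
        )

    def query(
        self, allele_query: AlleleQuery, credential: Optional[Credential] = None
    ) -> AlleleResponse:
        exists: Optional[bool] = None
        failures = 0
        for member in self._members:
            try:
                r = member.query(allele_query, credential)
            except Exception as exc:
                logger.warning("aggregate member failed: %s", exc)
                failures += 1
                continue
            if r.exists is True:
                exists = True
                break  # OR short-circuits; no member-count information leaks
            if r.exists is False and exists is None:
                exists = False
        if exists is None and failures == len(self._members):
            return AlleleResponse(
                beacon_id=self.beacon_id,
                exists=None,
                error=BeaconProtocolError("beacon_failure", "no member answered"),
            )
        if exists is None:
            # every member refused (consent/tier/budget): propagate the refusal
            return AlleleResponse(
                beacon_id=self.beacon_id,
                exists=None,
                error=BeaconProtocolError(
                    "all_datasets_denied", "no member was authorized to answer"
                ),
            )
        return AlleleResponse(beacon_id=self.beacon_id, exists=exists)


def make_aggregate(
    beacon_handles: Sequence[BeaconHandle], aggregate_id: str, **kwargs
) -> AggregateBeacon:
    """Fuse beacons into one origin-obscuring aggregate beacon."""
    return AggregateBeacon(beacon_handles, aggregate_id, **kwargs)


class HttpBeaconHandle:
    """Client-side handle for a beacon served over HTTP."""

    def __init__(self, base_url: str, timeout: float = DEFAULT_TIMEOUT_S):
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout

    def _get(self, path: str, params: Optional[dict] = None) -> dict:
        from urllib.parse import urlencode
        from urllib.request import urlopen

        url = f"{self.base_url}{path}"
        if params:
            url += "?" + urlencode(params)
        with urlopen(url, timeout=self.timeout) as reply:  # noqa: S310 (http by design)
            return json.loads(reply.read().decode())

    def info(self) -> BeaconInfo:
        payload = self._get("/")
        return BeaconInfo(
            beacon_id=payload["id"],
            organization=payload.get("organization", ""),
            description=payload.get("description", ""),
            api_version=payload.get("apiVersion", ""),
            datasets=[],  # dataset detail is not needed network-side
        )

    def query(
        self, allele_query: AlleleQuery, credential: Optional[Credential] = None
    ) -> AlleleResponse:
        from urllib.error import HTTPError

        params = {
            "assemblyId": allele_query.assembly_id,
            "referenceName": allele_query.chromosome,
            "start": str(allele_query.start),
            "referenceBases": allele_query.ref_bases,
            "alternateBases": allele_query.alt_bases,
        }
        if allele_query.dataset_ids:
            params["datasetIds"] = ",".join(allele_query.dataset_ids)
        if allele_query.include_dataset_responses:
            params["includeDatasetResponses"] = "true"
        params["purpose"] = allele_query.purpose.category.value
        if allele_query.purpose.disease_term:
            params["diseaseTerm"] = allele_query.purpose.disease_term
        if credential and credential.token:
            params["token"] = credential.token
        try:
            payload = self._get("/query", params)
        except HTTPError as exc:
            payload = json.loads(exc.read().decode())
        error = None
        if payload.get("error"):
            error = BeaconProtocolError(
                code=payload["error"].get("errorCode", "unknown"),
                message=payload["error"].get("message", ""),
            )
        return AlleleResponse(
            beacon_id=payload.get("beaconId", ""),
            exists=payload.get("exists"),
            error=error,
        )
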