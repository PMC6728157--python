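"""Service wiring: JSON configuration, index caching, and a small HTTP front.

A service config declares the beacon's identity, the VCF-backed datasets it
serves (each with a consent code and a minimum access tier), the token
registry, and the budget policy.  ``build_beacon`` turns a config into a live
:class:`~beaconkit.beacon_core.Beacon`, reusing a persisted index alongside
each VCF when it is newer than its source and rebuilding it otherwise.

The HTTP front is a thin shim over the pure request handlers in beacon_core:
GET / serves the info document, GET /query the allele query.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Dict, List, Optional, Tuple
from urllib.parse import parse_qsl, urlsplit

from . import allele_store as store
from .access_control import AccessTier, ConsentCategory, ConsentCode
from .beacon_core import Beacon, handle_info_request, handle_query_request
from .errors import ConfigError
from .privacy_budget import BudgetLedger, CostPolicy

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class DatasetDeclaration:
    path: Path
    dataset_id: str
    assembly_id: str
    consent_code: ConsentCode
    minimum_tier: AccessTier
    name: str = ""
    description: str = ""


@dataclass(slots=True)
class ServiceConfig:
    beacon_id: str
    organization: str = ""
    description: str = ""
    datasets: List[DatasetDeclaration] = field(default_factory=list)
    token_registry: Dict[str, AccessTier] = field(default_factory=dict)
    budget_threshold_bits: Optional[float] = None  # None disables metering
    cost_policy: CostPolicy = field(default_factory=CostPolicy)
    ledger_path: Optional[Path] = None
    log_level: str = "INFO"


def _parse_consent(raw: dict) -> ConsentCode:
    try:
        return ConsentCode(
            primary_category=ConsentCategory(raw.get("primary_category", "NRES")),
            disease_term=raw.get("disease_term"),
            secondary_requirements=tuple(raw.get("secondary_requirements", ())),
        )
    except ValueError as exc:
        raise ConfigError(f"bad consent code {raw!r}: {exc}") from exc


def load_service_config(path) -> ServiceConfig:
    """Parse and validate a service config JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if "beacon_id" not in raw or not raw["beacon_id"]:
        raise ConfigError("config field 'beacon_id' is required")
    datasets: List[DatasetDeclaration] = []
    seen_ids = set()
    for ds in raw.get("datasets", []):
        for required in ("path", "dataset_id", "assembly_id"):
            if required not in ds:
                raise ConfigError(f"dataset declaration missing field {required!r}")
        vcf_path = (path.parent / ds["path"]).resolve()
        if not vcf_path.exists():
            raise ConfigError(f"dataset VCF does not exist: {vcf_path}")
        if ds["dataset_id"] in seen_ids:
            raise ConfigError(f"duplicate dataset_id {ds['dataset_id']!r}")
        seen_ids.add(ds["dataset_id"])
        datasets.append(
            DatasetDeclaration(
                path=vcf_path,
                dataset_id=ds["dataset_id"],
                assembly_id=ds["assembly_id"],
                consent_code=_parse_consent(ds.get("consent", {})),
                minimum_tier=AccessTier.parse(ds.get("minimum_tier", "OPEN")),
                name=ds.get("name", ""),
                description=ds.get("description", ""),
            )
        )
    tokens = {
        token: AccessTier.parse(tier)
        for token, tier in raw.get("token_registry", {}).items()
    }
    budget = raw.get("budget", {})
    policy = CostPolicy(
        frequency_floor=budget.get("frequency_floor", 1e-4),
        no_response_cost=budget.get("no_response_cost", 0.05),
        unknown_frequency_cost=budget.get("unknown_frequency_cost"),
    )
    ledger_path = raw.get("ledger_path")
    return ServiceConfig(
        beacon_id=raw["beacon_id"],
        organization=raw.get("organization", ""),
        description=raw.get("description", ""),
        datasets=datasets,
        token_registry=tokens,
        budget_threshold_bits=budget.get("threshold_bits"),
        cost_policy=policy,
        ledger_path=(path.parent / ledger_path).resolve() if ledger_path else None,
        log_level=raw.get("log_level", "INFO"),
    )


def index_cache_path(vcf_path: Path) -> Path:
    return vcf_path.with_name(vcf_path.name + ".beaconidx.json")


def load_or_build_index(decl: DatasetDeclaration, persist: bool = True):
    """Reuse the persisted index when fresh; rebuild when the VCF is newer."""
    cache = index_cache_path(decl.path)
    if cache.exists() and cache.stat().st_mtime >= decl.path.stat().st_mtime:
        try:
            index = store.load_index(cache)
            if index.dataset_id == decl.dataset_id:
                logger.info("reusing index cache %s", cache)
                return index
        except Exception as exc:  # stale or corrupt cache: rebuild
            logger.warning("ignoring unusable index cache %s: %s", cache, exc)
    index = store.ingest_vcf(decl.path, decl.dataset_id, decl.assembly_id)
    if persist:
        store.save_index(index, cache)
    return index


def build_beacon(config: ServiceConfig) -> Beacon:
    ledger = None
    if config.budget_threshold_bits is not None:
        if config.ledger_path and config.ledger_path.exists():
            ledger = BudgetLedger.load(config.ledger_path)
        else:
            ledger = BudgetLedger(threshold_bits=config.budget_threshold_bits)
    beacon = Beacon(
        beacon_id=config.beacon_id,
        organization=config.organization,
        description=config.description,
        token_registry=config.token_registry,
        ledger=ledger,
        cost_policy=config.cost_policy,
    )
    for decl in config.datasets:
        beacon.add_dataset(
            load_or_build_index(decl),
            consent_code=decl.consent_code,
            minimum_tier=decl.minimum_tier,
            name=decl.name,
            description=decl.description,
        )
    return beacon


def load_registry(path) -> "BeaconRegistry":
    """Build a live network registry from a registry JSON file.

    Entries carry an ``id``, an ``organization``, and either a ``path`` to a
    local service config (the beacon runs in-process) or a ``url`` (the beacon
    is queried over HTTP).  Paths are resolved relative to the registry file.
    """
    from .network import BeaconRegistry, HttpBeaconHandle

    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read registry {path}: {exc}") from exc
    registry = BeaconRegistry()
    for entry in raw.get("beacons", []):
        if "url" in entry:
            handle = HttpBeaconHandle(entry["url"])
        elif "path" in entry:
            config_path = Path(entry["path"])
            if not config_path.is_absolute():
                config_path = path.parent / config_path
            handle = build_beacon(load_service_config(config_path))
        else:
            raise ConfigError(f"registry entry needs 'path' or 'url': {entry!r}")
        registry.register(handle, organization=entry.get("organization", ""))
    return registry


# ---------------------------------------------------------------------------
# HTTP front
# ---------------------------------------------------------------------------


def dispatch_request(beacon: Beacon, path_and_query: str) -> Tuple[int, dict]:
    """Route a raw request target to the protocol handlers (no sockets needed)."""
    parts = urlsplit(path_and_query)
    params = dict(parse_qsl(parts.query))
    token = params.pop("token", None)
    if parts.path in ("/", "/info"):
        return handle_info_request(beacon)
    if parts.path == "/query":
        return handle_query_request(beacon, params, token=token)
    return 404, {"error": {"errorCode": "not_found", "message": parts.path}}


def make_server(beacon: Beacon, host: str = "127.0.0.1", port: int = 0):
    """A ThreadingHTTPServer serving the two beacon routes as JSON."""

    class Handler(BaseHTTPRequestHandler):
        def do_GET(self):  # noqa: N802 (stdlib naming)
            status, payload = dispatch_request(beacon, self.path)
            body = json.dumps(payload).encode()
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, fmt, *args):
            logger.debug("http: " + fmt, *args)

    return ThreadingHTTPServer((host, port), Handler)
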