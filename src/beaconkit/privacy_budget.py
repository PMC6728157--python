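"""Information budgeting: meter per-credential disclosure and lock out callers.

Membership-inference attacks accumulate evidence over many queries, and the
evidence per query grows as the queried allele gets rarer.  The meter prices a
"yes" at the allele's surprisal, -log2(frequency), floored at a configurable
minimum frequency so no single answer is priced as infinitely informative; a
"no" costs a small constant because repeated "no"s also inform an attacker.
When a credential's cumulative spend reaches the ledger threshold it is locked
out: the query that crosses the threshold is still answered (charge-then-lock),
every later one is refused before any lookup happens.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Set

from .errors import DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class CostPolicy:
    """Pricing of a single answered query, in bits.

    ``frequency_floor`` caps the price of very rare alleles (default 1e-4,
    i.e. at most ~13.3 bits per "yes"); ``no_response_cost`` is the flat price
    of a "no"; ``unknown_frequency_cost`` is charged when a "yes" carries no
    frequency and defaults to the price at the floor (the most conservative
    monotone choice).
    """

    frequency_floor: float = 1e-4
    no_response_cost: float = 0.05
    unknown_frequency_cost: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.frequency_floor < 1.0):
            raise DomainError(f"frequency_floor must be in (0,1), got {self.frequency_floor}")
        if self.no_response_cost < 0:
            raise DomainError("no_response_cost must be >= 0")
        if self.unknown_frequency_cost is not None and self.unknown_frequency_cost < 0:
            raise DomainError("unknown_frequency_cost must be >= 0")

    @property
    def resolved_unknown_cost(self) -> float:
        if self.unknown_frequency_cost is not None:
            return self.unknown_frequency_cost
        return -math.log2(self.frequency_floor)

    @property
    def min_cost(self) -> float:
        """Smallest possible price of an answered query (for exhaustion bounds)."""
        return min(self.no_response_cost, 1.0)  # max frequency 0.5 -> 1 bit "yes"


def query_cost(
    frequency: Optional[float], response_is_yes: bool, policy: CostPolicy
) -> float:
    """Bits charged for one answered query.

    A "yes" at frequency f costs -log2(max(f, floor)); a "yes" with no
    frequency available costs the unknown-frequency price; a "no" costs the
    flat no-response price.  Strictly decreasing in f above the floor.
    """
    if not response_is_yes:
        return policy.no_response_cost
    if frequency is None:
        return policy.resolved_unknown_cost
    if not (0.0 < frequency <= 1.0):
        raise DomainError(f"frequency must be in (0,1], got {frequency}")
    return -math.log2(max(frequency, policy.frequency_floor))


@dataclass(slots=True)
class BudgetLedger:
    """Cumulative per-credential disclosure, with a lockout threshold in bits."""

    threshold_bits: float = 30.0
    spent: Dict[str, float] = field(default_factory=dict)
    locked: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.threshold_bits <= 0:
            raise DomainError("threshold_bits must be positive")

    def is_locked(self, identity_key: str) -> bool:
        return identity_key in self.locked

    def charge_and_gate(self, identity_key: str, cost: float) -> bool:
        """Charge ``cost`` bits and return whether the query may be answered.

        A locked key is refused without charging.  Otherwise the key is charged
        first and locked afterwards if its spend reached the threshold, so the
        crossing query itself is still answered.
        """
        if cost < 0:
            raise DomainError("cost must be >= 0")
        if identity_key in self.locked:
            return False
        self.spent[identity_key] = self.spent.get(identity_key, 0.0) + cost
        if self.spent[identity_key] >= self.threshold_bits:
            self.locked.add(identity_key)
            logger.info("budget exhausted for %s (%.2f bits)", identity_key,
                        self.spent[identity_key])
        return True

    def reset(self, identity_key: str) -> "BudgetLedger":
        """Administrative unlock; clears the key's spend. No-op on unknown keys."""
        self.spent.pop(identity_key, None)
        self.locked.discard(identity_key)
        logger.info("budget reset for %s", identity_key)
        return self

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "threshold_bits": self.threshold_bits,
                    "spent": self.spent,
                    "locked": sorted(self.locked),
                }
            )
        )

    @classmethod
    def load(cls, path) -> "BudgetLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            threshold_bits=float(payload["threshold_bits"]),
            spent={k: float(v) for k, v in payload.get("spent", {}).items()},
            locked=set(payload.get("locked", [])),
        )
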