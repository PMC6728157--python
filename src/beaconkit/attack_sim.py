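"""Membership-inference attack simulation against beacons.

The re-identification threat model: an adversary who already holds a target's
genotypes queries a beacon repeatedly for alleles the target carries, and
accumulates evidence that the target's genome is in the served dataset.  This
module simulates diploid populations with a known allele-frequency spectrum,
builds beacon oracles from chosen member subsets, runs the two classic attack
statistics, and measures detection power at a calibrated false-positive rate —
including paired runs with and without the information-budget defense in the
query path.

Model assumptions: sites are independent (no linkage disequilibrium), each
individual's dosage at a site is Binomial(2, f), and the beacon answers "yes"
iff any member carries at least one alternate copy, after an optional per-copy
dropout (mismatch) rate delta that models discordance between the attacker's
copy of the target genome and the beacon's.

Two statistics are implemented:

* frequency-aware likelihood-ratio:  for responses x_i at frequencies f_i,

      L = sum_i [ x_i * ln(Pin_i/Pout_i) + (1-x_i) * ln((1-Pin_i)/(1-Pout_i)) ]

  with Pout_i = 1-(1-f_i)^(2N) (an allele's presence probability in a beacon
  of N non-member diploids) and Pin_i = 1-delta*(1-f_i)^(2(N-1)) (presence
  given the target is a member, up to the mismatch rate).  delta > 0 keeps the
  "no" branch finite.  The attacker queries rarest alleles first.

* frequency-agnostic count: the fraction of "yes" responses, queried in random
  order; needs no frequency knowledge at all.

Decision thresholds are calibrated empirically: the (1-alpha) quantile of the
non-member statistic distribution, so the achieved false-positive rate is at
most alpha by construction.  Power is the fraction of member trials strictly
above that threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError
from .privacy_budget import CostPolicy

logger = logging.getLogger(__name__)

FREQUENCY_AWARE_LRT = "frequency_aware_lrt"
FREQUENCY_AGNOSTIC_COUNT = "frequency_agnostic_count"
_ATTACK_KINDS = (FREQUENCY_AWARE_LRT, FREQUENCY_AGNOSTIC_COUNT)


# ---------------------------------------------------------------------------
# Synthetic populations
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class SyntheticPopulation:
    """Simulated diploid genotypes with a known allele-frequency spectrum.

    ``genotypes`` is an (n_individuals, n_snps) int8 matrix of alt-allele
    dosages in {0,1,2}; ``frequencies`` the true per-site alt frequencies.
    """

    n_individuals: int
    n_snps: int
    frequencies: np.ndarray
    genotypes: np.ndarray
    seed: int
    f_min: float = 1e-3
    afs_shape: Tuple[float, float] = (0.5, 0.5)


def simulate_population(
    n_individuals: int,
    n_snps: int,
    afs_shape: Tuple[float, float] = (0.5, 0.5),
    f_min: float = 1e-3,
    seed: int = 0,
) -> SyntheticPopulation:
    """Draw a population with frequencies from a truncated Beta spectrum.

    Per-site frequencies are Beta(a, b) truncated (by inverse-CDF restriction)
    to [f_min, 0.5]; dosages are two independent Bernoulli(f) draws per
    individual, i.e. Binomial(2, f).  Fully reproducible from ``seed``.
    """
    if n_individuals < 1 or n_snps < 1:
        raise DomainError("n_individuals and n_snps must be positive")
    a, b = afs_shape
    if a <= 0 or b <= 0:
        raise DomainError("afs_shape parameters must be positive")
    if not (0.0 < f_min <= 0.5):
        raise DomainError(f"f_min must be in (0, 0.5], got {f_min}")
    rng = np.random.default_rng(seed)
    lo, hi = sps.beta.cdf([f_min, 0.5], a, b)
    u = rng.uniform(lo, hi, size=n_snps)
    frequencies = np.clip(sps.beta.ppf(u, a, b), f_min, 0.5)
    genotypes = rng.binomial(2, frequencies, size=(n_individuals, n_snps)).astype(
        np.int8
    )
    return SyntheticPopulation(
        n_individuals=n_individuals,
        n_snps=n_snps,
        frequencies=frequencies,
        genotypes=genotypes,
        seed=seed,
        f_min=f_min,
        afs_shape=(a, b),
    )


@dataclass(slots=True)
class BeaconOracle:
    """Yes/no oracle over one simulated beacon membership.

    ``alt_copies`` holds the per-site alt-allele copy counts among members
    after dropout; the oracle answers yes wherever at least one copy survives.
    """

    presence: np.ndarray  # bool per site
    alt_copies: np.ndarray  # int per site
    n_members: int

    def query_site(self, site: int) -> bool:
        return bool(self.presence[site])

    def allele_frequency(self, site: int) -> float:
        """The beacon's own (member-based) allele frequency at a site."""
        return float(self.alt_copies[site]) / (2.0 * self.n_members) if self.n_members else 0.0


def beacon_from_population(
    population: SyntheticPopulation,
    member_ids: Sequence[int],
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> BeaconOracle:
    """Build the presence oracle for a member subset.

    Each alt-allele copy held by a member is independently lost with
    probability ``dropout`` (the mismatch rate between the attacker's copy of
    a genome and the beacon's).  An empty membership yields an all-"no" oracle.
    """
    member_ids = np.asarray(member_ids, dtype=np.intp)
    if member_ids.size == 0:
        zero = np.zeros(population.n_snps, dtype=np.int64)
        return BeaconOracle(presence=zero > 0, alt_copies=zero, n_members=0)
    if member_ids.min() < 0 or member_ids.max() >= population.n_individuals:
        raise DomainError("member_ids outside population")
    counts = population.genotypes[member_ids].sum(axis=0, dtype=np.int64)
    if dropout > 0.0:
        if rng is None:
            rng = np.random.default_rng(population.seed)
        counts = rng.binomial(counts, 1.0 - dropout)
    return BeaconOracle(
        presence=counts > 0, alt_copies=counts, n_members=int(member_ids.size)
    )


# ---------------------------------------------------------------------------
# Attack statistics
# ---------------------------------------------------------------------------


def _lrt_terms(
    responses: np.ndarray,
    queried_frequencies: np.ndarray,
    n_members: int,
    mismatch_rate: float,
) -> np.ndarray:
    """Per-query log-likelihood-ratio contributions (vectorized, underflow-safe)."""
    x = np.asarray(responses, dtype=bool)
    f = np.asarray(queried_frequencies, dtype=float)
    if x.shape != f.shape:
        raise DomainError("responses and queried_frequencies must align")
    if np.any((f <= 0) | (f >= 1)):
        raise DomainError("queried frequencies must be in (0,1)")
    if n_members < 1:
        raise DomainError("n_members must be >= 1")
    delta = mismatch_rate
    if not (0.0 < delta < 1.0):
        if np.any(~x):
            raise DomainError(
                "mismatch_rate must be in (0,1): a 'no' response has zero "
                "likelihood under membership when delta == 0"
            )
        delta = 1e-300  # all-yes: the no-branch is never evaluated
    log1mf = np.log1p(-f)
    log_one_minus_pout = 2 * n_members * log1mf  # ln (1-f)^{2N}
    one_minus_pout = np.exp(log_one_minus_pout)
    log_pout = np.log1p(-one_minus_pout)
    log_one_minus_pin = math.log(delta) + 2 * (n_members - 1) * log1mf
    log_pin = np.log1p(-np.exp(log_one_minus_pin))
    yes_terms = log_pin - log_pout
    no_terms = log_one_minus_pin - log_one_minus_pout
    return np.where(x, yes_terms, no_terms)


def lrt_statistic(
    responses: Sequence[bool],
    queried_frequencies: Sequence[float],
    n_members: int,
    mismatch_rate: float = 1e-6,
) -> float:
    """Frequency-aware membership log-likelihood ratio (larger => member).

    Zero queries give an empty sum, 0.0.  ``mismatch_rate`` must be positive
    whenever any response is "no".
    """
    if len(responses) == 0:
        return 0.0
    return float(
        _lrt_terms(
            np.asarray(responses), np.asarray(queried_frequencies), n_members,
            mismatch_rate,
        ).sum()
    )


def count_statistic(responses: Sequence[bool]) -> float:
    """Frequency-agnostic statistic: the fraction of "yes" responses."""
    x = np.asarray(responses, dtype=bool)
    if x.size == 0:
        raise DomainError("count_statistic requires at least one response")
    return float(x.mean())


# ---------------------------------------------------------------------------
# Attack experiments
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class AttackConfig:
    """One attack scenario.

    ``mismatch_rate`` (delta) is the per-copy probability that a target allele
    copy is missing from the beacon's copy of their genome; ``fpr_target``
    (alpha) the tolerated false-positive rate; ``freq_range`` optionally
    restricts queries to alleles with population frequency in [lo, hi);
    ``null_calibration`` draws both "member" and "non-member" targets from
    outside the beacon, so any detected power is a calibration artifact.
    """

    attack_kind: str = FREQUENCY_AGNOSTIC_COUNT
    n_queries: int = 1000
    beacon_size: int = 1000
    mismatch_rate: float = 1e-6
    fpr_target: float = 0.05
    n_replicates: int = 100
    seed: int = 0
    freq_range: Optional[Tuple[float, float]] = None
    null_calibration: bool = False

    def __post_init__(self):
        if self.attack_kind not in _ATTACK_KINDS:
            raise DomainError(f"unknown attack_kind {self.attack_kind!r}")
        if self.n_queries < 1:
            raise DomainError("n_queries must be >= 1")
        if self.beacon_size < 1:
            raise DomainError("beacon_size must be >= 1")
        if not (0.0 < self.mismatch_rate < 1.0):
            raise DomainError("mismatch_rate must be in (0,1)")
        if not (0.0 < self.fpr_target < 1.0):
            raise DomainError("fpr_target must be in (0,1)")
        if self.n_replicates < 2:
            raise DomainError("n_replicates must be >= 2")


@dataclass(slots=True)
class AttackResult:
    """Per-trial statistics plus the calibrated decision summary."""

    statistics_members: np.ndarray
    statistics_nonmembers: np.ndarray
    threshold: float
    power: float
    achieved_fpr: float
    config: AttackConfig

    def summary(self) -> dict:
        return {
            "attack_kind": self.config.attack_kind,
            "n_queries": self.config.n_queries,
            "beacon_size": self.config.beacon_size,
            "n_replicates": self.config.n_replicates,
            "fpr_target": self.config.fpr_target,
            "threshold": self.threshold,
            "power": self.power,
            "achieved_fpr": self.achieved_fpr,
        }


def _calibrate(
    member_stats: np.ndarray, nonmember_stats: np.ndarray, alpha: float
) -> Tuple[float, float, float]:
    """Empirical-quantile threshold; guarantees achieved FPR <= alpha."""
    threshold = float(np.quantile(nonmember_stats, 1.0 - alpha, method="higher"))
    power = float(np.mean(member_stats > threshold))
    achieved_fpr = float(np.mean(nonmember_stats > threshold))
    return threshold, power, achieved_fpr


def _draw_replicate(
    population: SyntheticPopulation, config: AttackConfig, rng: np.random.Generator
):
    """Membership, a member target, a non-member target, and the oracle."""
    n = population.n_individuals
    needed = config.beacon_size + 2
    if n < needed:
        raise DomainError(
            f"population of {n} too small for beacon_size {config.beacon_size} "
            "plus disjoint member/non-member targets"
        )
    perm = rng.permutation(n)
    if config.null_calibration:
        target_a, target_b = int(perm[0]), int(perm[1])
        members = perm[2 : 2 + config.beacon_size]
    else:
        members = perm[: config.beacon_size]
        target_a = int(members[rng.integers(config.beacon_size)])
        target_b = int(perm[config.beacon_size + rng.integers(n - config.beacon_size)])
    oracle = beacon_from_population(
        population, members, dropout=config.mismatch_rate, rng=rng
    )
    return members, target_a, target_b, oracle


def _ordered_query_positions(
    population: SyntheticPopulation,
    target: int,
    config: AttackConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """The target's alt-carried sites in the attacker's query order."""
    positions = np.flatnonzero(population.genotypes[target] > 0)
    if config.freq_range is not None:
        lo, hi = config.freq_range
        f = population.frequencies[positions]
        positions = positions[(f >= lo) & (f < hi)]
    if config.attack_kind == FREQUENCY_AWARE_LRT:
        order = np.argsort(population.frequencies[positions], kind="stable")
        return positions[order]  # rarest first
    return rng.permutation(positions)


def _statistic(
    population: SyntheticPopulation,
    oracle: BeaconOracle,
    positions: np.ndarray,
    config: AttackConfig,
) -> float:
    responses = oracle.presence[positions]
    if config.attack_kind == FREQUENCY_AWARE_LRT:
        return lrt_statistic(
            responses,
            population.frequencies[positions],
            oracle.n_members,
            config.mismatch_rate,
        )
    return count_statistic(responses)


def run_attack(population: SyntheticPopulation, config: AttackConfig) -> AttackResult:
    """Monte-Carlo power estimate for one attack scenario.

    Each replicate draws a fresh beacon membership, one member target and one
    non-member target, queries ``n_queries`` of each target's alt-carried
    positions (truncated with a warning if a target carries fewer), and
    computes the configured statistic.  The threshold is the (1-alpha)
    empirical quantile of the non-member statistics.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    member_stats = np.empty(config.n_replicates)
    nonmember_stats = np.empty(config.n_replicates)
    truncated = False
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        _, target_a, target_b, oracle = _draw_replicate(population, config, rng)
        for target, out in ((target_a, member_stats), (target_b, nonmember_stats)):
            positions = _ordered_query_positions(population, target, config, rng)
            if positions.size == 0:
                raise DomainError(
                    "target carries no queryable alt alleles under this config"
                )
            if positions.size < config.n_queries:
                truncated = True
            out[r] = _statistic(
                population, oracle, positions[: config.n_queries], config
            )
    if truncated:
        warnings.warn(
            "n_queries exceeds some targets' alt-carried positions; truncated",
            stacklevel=2,
        )
    threshold, power, achieved_fpr = _calibrate(
        member_stats, nonmember_stats, config.fpr_target
    )
    return AttackResult(
        statistics_members=member_stats,
        statistics_nonmembers=nonmember_stats,
        threshold=threshold,
        power=power,
        achieved_fpr=achieved_fpr,
        config=config,
    )


# ---------------------------------------------------------------------------
# Query-count sweeps
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class QuerySweep:
    """Result of a doubling-then-bisection sweep over query counts.

    ``n_queries`` is the smallest count reaching the power goal, or None when
    the goal is not reached within ``cap`` (the largest count any target could
    actually be asked).
    """

    n_queries: Optional[int]
    cap: int
    power_at_cap: float
    power_goal: float


class _PrefixStats:
    """Per-replicate cumulative statistics, so power(n) is O(replicates)."""

    def __init__(self, population: SyntheticPopulation, config: AttackConfig):
        self.alpha = config.fpr_target
        self.member_cums: List[np.ndarray] = []
        self.nonmember_cums: List[np.ndarray] = []
        children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
        for child in children:
            rng = np.random.default_rng(child)
            _, target_a, target_b, oracle = _draw_replicate(population, config, rng)
            for target, store in (
                (target_a, self.member_cums),
                (target_b, self.nonmember_cums),
            ):
                positions = _ordered_query_positions(population, target, config, rng)
                if positions.size == 0:
                    raise DomainError("target carries no queryable alt alleles")
                responses = oracle.presence[positions]
                if config.attack_kind == FREQUENCY_AWARE_LRT:
                    terms = _lrt_terms(
                        responses,
                        population.frequencies[positions],
                        oracle.n_members,
                        config.mismatch_rate,
                    )
                    store.append(np.cumsum(terms))
                else:
                    store.append(
                        np.cumsum(responses) / np.arange(1, responses.size + 1)
                    )
        self.cap = int(max(c.size for c in self.member_cums + self.nonmember_cums))

    def _stats_at(self, cums: List[np.ndarray], n: int) -> np.ndarray:
        return np.array([c[min(n, c.size) - 1] for c in cums])

    def power_at(self, n: int) -> float:
        _, power, _ = _calibrate(
            self._stats_at(self.member_cums, n),
            self._stats_at(self.nonmember_cums, n),
            self.alpha,
        )
        return power


def sweep_queries_needed(
    population: SyntheticPopulation,
    config: AttackConfig,
    power_goal: float = 0.95,
    cap: Optional[int] = None,
) -> QuerySweep:
    """Smallest query count reaching ``power_goal``, by doubling then bisection.

    The same replicate draws (same seed) are reused across all counts: each
    target's full ordered response sequence is computed once and the statistic
    at any n is read off its prefix.  Counts beyond a target's carried
    positions plateau at the full-sequence statistic.
    """
    if not (0.0 < power_goal < 1.0):
        raise DomainError("power_goal must be in (0,1)")
    prefix = _PrefixStats(population, config)
    hard_cap = prefix.cap if cap is None else min(cap, prefix.cap)
    power_at_cap = prefix.power_at(hard_cap)
    # doubling phase
    n = 1
    found = None
    while n <= hard_cap:
        if prefix.power_at(n) >= power_goal:
            found = n
            break
        n *= 2
    if found is None:
        if power_at_cap >= power_goal:
            found = hard_cap
        else:
            return QuerySweep(None, hard_cap, power_at_cap, power_goal)
    # bisection for the smallest count in (found//2, found]
    lo, hi = max(1, found // 2), found
    while lo < hi:
        mid = (lo + hi) // 2
        if prefix.power_at(mid) >= power_goal:
            hi = mid
        else:
            lo = mid + 1
    return QuerySweep(int(hi), hard_cap, power_at_cap, power_goal)


def queries_needed(
    population: SyntheticPopulation,
    config: AttackConfig,
    power_goal: float = 0.95,
    cap: Optional[int] = None,
) -> Optional[int]:
    """Convenience wrapper around :func:`sweep_queries_needed`; None = not reached."""
    return sweep_queries_needed(population, config, power_goal, cap).n_queries


# ---------------------------------------------------------------------------
# Budget defense evaluation
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class DefenseComparison:
    """Paired attack results with and without the information-budget gate."""

    undefended: AttackResult
    defended: AttackResult
    answered_members: np.ndarray
    answered_nonmembers: np.ndarray
    threshold_bits: float
    policy: CostPolicy

    def summary(self) -> dict:
        return {
            "threshold_bits": self.threshold_bits,
            "undefended": self.undefended.summary(),
            "defended": self.defended.summary(),
            "max_answered_queries": int(
                max(self.answered_members.max(), self.answered_nonmembers.max())
            ),
        }


def _answered_count(costs: np.ndarray, threshold_bits: float) -> int:
    """How many queries get answered under charge-then-lock metering."""
    if not math.isfinite(threshold_bits):
        return costs.size
    spent = np.cumsum(costs)
    crossing = int(np.searchsorted(spent, threshold_bits, side="left"))
    return min(crossing + 1, costs.size)  # the crossing query is still answered


def evaluate_defense(
    population: SyntheticPopulation,
    config: AttackConfig,
    budget_policy: Optional[CostPolicy] = None,
    threshold_bits: float = 30.0,
) -> DefenseComparison:
    """Run the same attack with and without budget metering in the query path.

    Both arms share every random draw (membership, targets, query order), so
    the comparison is paired.  In the defended arm each answered query is
    priced from the beacon's own member-based allele frequency ("yes") or the
    flat no-response cost ("no"); once the cumulative spend crosses the
    threshold the session is over and later queries contribute no evidence —
    the defended statistic is computed over the answered prefix only.  An
    infinite threshold reproduces the undefended result exactly.
    """
    policy = budget_policy or CostPolicy()
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    stats = {
        "undefended": (np.empty(config.n_replicates), np.empty(config.n_replicates)),
        "defended": (np.empty(config.n_replicates), np.empty(config.n_replicates)),
    }
    answered = (
        np.empty(config.n_replicates, dtype=int),
        np.empty(config.n_replicates, dtype=int),
    )
    floor = policy.frequency_floor
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        _, target_a, target_b, oracle = _draw_replicate(population, config, rng)
        for t_idx, target in enumerate((target_a, target_b)):
            positions = _ordered_query_positions(population, target, config, rng)[
                : config.n_queries
            ]
            if positions.size == 0:
                raise DomainError("target carries no queryable alt alleles")
            responses = oracle.presence[positions]
            beacon_af = oracle.alt_copies[positions] / (2.0 * oracle.n_members)
            costs = np.where(
                responses,
                -np.log2(np.maximum(beacon_af, floor)),
                policy.no_response_cost,
            )
            k = _answered_count(costs, threshold_bits)
            answered[t_idx][r] = k
            stats["undefended"][t_idx][r] = _statistic(
                population, oracle, positions, config
            )
            stats["defended"][t_idx][r] = _statistic(
                population, oracle, positions[:k], config
            )

    def _result(arm: str) -> AttackResult:
        member, nonmember = stats[arm]
        threshold, power, fpr = _calibrate(member, nonmember, config.fpr_target)
        return AttackResult(
            statistics_members=member,
            statistics_nonmembers=nonmember,
            threshold=threshold,
            power=power,
            achieved_fpr=fpr,
            config=config,
        )

    return DefenseComparison(
        undefended=_result("undefended"),
        defended=_result("defended"),
        answered_members=answered[0],
        answered_nonmembers=answered[1],
        threshold_bits=threshold_bits,
        policy=policy,
    )


# ---------------------------------------------------------------------------
# Exports and the VCF fixture writer
# ---------------------------------------------------------------------------


def attack_result_frame(result: AttackResult) -> pd.DataFrame:
    """One row per replicate: the member and non-member statistics."""
    n = result.statistics_members.size
    return pd.DataFrame(
        {
            "replicate": np.arange(n),
            "member_statistic": result.statistics_members,
            "nonmember_statistic": result.statistics_nonmembers,
        }
    )


_REF_BASES = "ACGT"
_ALT_BASES = "CGTA"  # alt differs from ref at every cycle position


def write_vcf(
    population: SyntheticPopulation, member_ids: Sequence[int], path
) -> Path:
    """Write the members' genotypes as a VCF v4.2 text file.

    One line per site segregating among the members (site index i maps to
    POS i+1 on contig "1"), GT columns for every member, and INFO AC/AN
    consistent with the genotypes.  An empty membership yields a header-only
    file.
    """
    path = Path(path)
    member_ids = np.asarray(sorted(int(m) for m in member_ids), dtype=np.intp)
    if member_ids.size and (
        member_ids.min() < 0 or member_ids.max() >= population.n_individuals
    ):
        raise DomainError("member_ids outside population")
    header = [
        "##fileformat=VCFv4.2",
        "##source=beaconkit-synthetic-population",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
    ]
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if member_ids.size:
        columns += ["FORMAT"] + [f"S{int(m)}" for m in member_ids]
    lines = header + ["\t".join(columns)]
    if member_ids.size:
        sub = population.genotypes[member_ids]
        an = 2 * member_ids.size
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for site in np.flatnonzero(sub.any(axis=0)):
            dosages = sub[:, site]
            ac = int(dosages.sum())
            fields = [
                "1",
                str(site + 1),
                ".",
                _REF_BASES[site % 4],
                _ALT_BASES[site % 4],
                ".",
                ".",
                f"AC={ac};AN={an}",
                "GT",
            ] + [gt_strings[int(d)] for d in dosages]
            lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def population_allele_keys(
    population: SyntheticPopulation, member_ids: Sequence[int], assembly_id: str
):
    """The (chromosome, start, ref, alt) tuples :func:`write_vcf` emits.

    0-based starts, matching the public query convention. Useful as the ground
    truth for round-trip checks against an ingested fixture.
    """
    member_ids = np.asarray(sorted(int(m) for m in member_ids), dtype=np.intp)
    if member_ids.size == 0:
        return []
    sub = population.genotypes[member_ids]
    return [
        ("1", int(site), _REF_BASES[site % 4], _ALT_BASES[site % 4])
        for site in np.flatnonzero(sub.any(axis=0))
    ]
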