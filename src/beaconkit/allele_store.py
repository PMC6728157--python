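"""Exact-match allele indexes built from VCF files.

A beacon answers "have you observed this allele?" with exact-match semantics,
so the store reduces a VCF to a map from a canonical :class:`AlleleKey` to one
:class:`ObservationRecord` per observed alternate allele.  Canonicalization is
a reference-free trim (shared suffix, then shared prefix) of the REF/ALT pair,
the same convention used for matching SNVs and small indels without requiring
a FASTA reference for left-alignment.

Coordinates: the public API is 0-based (``start`` is the first reference base
of the allele); VCF POS is 1-based and converted once, at ingest or at query
normalization.  Contig names are stored without any leading ``chr``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Optional

import pysam

from .errors import (
    AssemblyMismatchError,
    DegenerateAlleleError,
    IngestError,
    UnsupportedAlleleError,
)

logger = logging.getLogger(__name__)

_ACGT_RE = re.compile(r"^[ACGT]+$")

INDEX_FORMAT_VERSION = 1


@dataclass(frozen=True, slots=True)
class AlleleKey:
    """Canonical identity of an allele.

    ``start`` is the 0-based position of the first reference base; ``ref_bases``
    and ``alt_bases`` are non-empty uppercase ACGT strings that differ after
    normalization.
    """

    assembly_id: str
    chromosome: str
    start: int
    ref_bases: str
    alt_bases: str


@dataclass(slots=True)
class ObservationRecord:
    """Observation evidence for one allele in one dataset.

    ``allele_count`` is the number of observed alternate-allele copies and
    ``call_count`` the total called copies at the site (VCF AC/AN semantics);
    either may be absent when the source VCF carries neither INFO counts nor
    genotypes.  ``sample_count`` is the number of individuals carrying the
    allele, computable only from genotype columns.
    """

    key: AlleleKey
    allele_count: Optional[int] = None
    call_count: Optional[int] = None
    sample_count: Optional[int] = None
    extra_metadata: Dict[str, str] = field(default_factory=dict)


@dataclass(slots=True)
class DatasetIndex:
    """Queryable exact-match map from :class:`AlleleKey` to observations."""

    dataset_id: str
    assembly_id: str
    records: Dict[AlleleKey, ObservationRecord] = field(default_factory=dict)
    sample_total: Optional[int] = None
    source_path: str = ""

    @property
    def record_count(self) -> int:
        return len(self.records)


def strip_chr(chromosome: str) -> str:
    """Drop a leading 'chr' (any case) for dialect tolerance between VCF sources."""
    if chromosome.lower().startswith("chr"):
        return chromosome[3:]
    return chromosome


def normalize_allele(
    chromosome: str,
    pos_1based: int,
    ref: str,
    alt: str,
    assembly_id: str,
) -> AlleleKey:
    """Canonicalize an allele into an :class:`AlleleKey`.

    Uppercases both base strings, validates them against ``[ACGT]+``, trims
    shared trailing bases, then shared leading bases (advancing ``start``),
    always leaving at least one base on each side, and converts the 1-based
    input position to a 0-based start.

    Raises
    ------
    UnsupportedAlleleError
        For symbolic alleles, breakends, N, or any non-ACGT character.
    DegenerateAlleleError
        When ref equals alt after trimming.
    ValueError
        For an empty chromosome or a position < 1.
    """
    chromosome = strip_chr(str(chromosome).strip())
    if not chromosome:
        raise ValueError("chromosome must be nonempty")
    if pos_1based < 1:
        raise ValueError(f"pos_1based must be >= 1, got {pos_1based}")
    ref = ref.upper()
    alt = alt.upper()
    for bases, label in ((ref, "ref"), (alt, "alt")):
        if not _ACGT_RE.match(bases):
            raise UnsupportedAlleleError(
                f"unsupported {label} allele {bases!r}: only [ACGT]+ is queryable"
            )
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix, advancing start
    start = pos_1based - 1
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if ref == alt:
        raise DegenerateAlleleError(
            f"degenerate allele at {chromosome}:{pos_1based}: ref == alt after trimming"
        )
    return AlleleKey(
        assembly_id=assembly_id,
        chromosome=chromosome,
        start=start,
        ref_bases=ref,
        alt_bases=alt,
    )


def allele_frequency(record: ObservationRecord) -> Optional[float]:
    """AC/AN when both counts are present, else ``None``."""
    if record.allele_count is None or record.call_count is None:
        return None
    if record.call_count <= 0:
        return None
    return record.allele_count / record.call_count


def lookup(index: DatasetIndex, key: AlleleKey) -> Optional[ObservationRecord]:
    """Exact-match lookup; ``None`` marks absence (never an error).

    Raises :class:`AssemblyMismatchError` when the key was normalized against a
    different assembly than the index serves — a silent "no" here would be a
    protocol lie.
    """
    if key.assembly_id != index.assembly_id:
        raise AssemblyMismatchError(
            f"key assembly {key.assembly_id!r} != index assembly {index.assembly_id!r}"
        )
    return index.records.get(key)


def _merge_record(index: DatasetIndex, rec: ObservationRecord) -> None:
    existing = index.records.get(rec.key)
    if existing is None:
        index.records[rec.key] = rec
        return
    logger.warning(
        "duplicate normalized key %s in %s: merging counts by summation",
        rec.key,
        index.source_path,
    )

    def _add(a: Optional[int], b: Optional[int]) -> Optional[int]:
        if a is None or b is None:
            return None
        return a + b

    existing.allele_count = _add(existing.allele_count, rec.allele_count)
    existing.call_count = _add(existing.call_count, rec.call_count)
    existing.sample_count = _add(existing.sample_count, rec.sample_count)
    existing.extra_metadata.update(rec.extra_metadata)


def _info_to_flat(info, skip=("AC", "AN")) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for k, v in info.items():
        if k in skip:
            continue
        if isinstance(v, (tuple, list)):
            out[k] = ",".join(str(x) for x in v)
        else:
            out[k] = str(v)
    return out


def _counts_from_genotypes(variant, alt_index: int):
    """(allele_count, call_count, sample_count) from GT columns, or Nones."""
    if not variant.samples:
        return None, None, None
    target = alt_index + 1  # GT allele index of this ALT
    ac = 0
    an = 0
    carriers = 0
    for sample in variant.samples.values():
        gt = sample.get("GT")
        if gt is None:
            continue
        has = False
        for allele in gt:
            if allele is None:
                continue
            an += 1
            if allele == target:
                ac += 1
                has = True
        if has:
            carriers += 1
    if an == 0:
        return None, None, None
    return ac, an, (carriers if carriers > 0 else None)


def ingest_vcf(path, dataset_id: str, assembly_id: str) -> DatasetIndex:
    """Build a :class:`DatasetIndex` from a VCF (plain or bgzipped).

    Multi-allelic lines are split per ALT; each (record, ALT) pair is
    normalized into an :class:`AlleleKey`.  Allele/call counts come from INFO
    AC/AN when present (producer-asserted counts take precedence), otherwise
    from GT columns, otherwise they are absent.  Symbolic or otherwise
    unsupported ALTs are skipped with a warning, never a crash; duplicate
    normalized keys are merged by summing counts.
    """
    path = Path(path)
    index = DatasetIndex(
        dataset_id=dataset_id, assembly_id=assembly_id, source_path=str(path)
    )
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise IngestError(f"cannot open {path} as VCF: {exc}") from exc
    with vcf:
        index.sample_total = len(vcf.header.samples) or None
        record_no = 0
        iterator: Iterator = iter(vcf)
        while True:
            try:
                variant = next(iterator)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise IngestError(
                    f"garbled VCF {path} near record {record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            alts = variant.alts or ()
            info_ac = variant.info.get("AC") if "AC" in variant.info else None
            if info_ac is not None and not isinstance(info_ac, tuple):
                info_ac = (info_ac,)
            info_an = variant.info.get("AN") if "AN" in variant.info else None
            extra = _info_to_flat(variant.info)
            for alt_index, alt in enumerate(alts):
                try:
                    key = normalize_allele(
                        variant.chrom, variant.pos, variant.ref, str(alt), assembly_id
                    )
                except (UnsupportedAlleleError, DegenerateAlleleError) as exc:
                    logger.warning(
                        "skipping unsupported ALT at %s:%s in %s: %s",
                        variant.chrom,
                        variant.pos,
                        path,
                        exc,
                    )
                    continue
                if info_ac is not None and alt_index < len(info_ac):
                    ac = int(info_ac[alt_index])
                    an = int(info_an) if info_an is not None else None
                    # carrier count is only derivable from genotypes
                    _, _, sc = _counts_from_genotypes(variant, alt_index)
                else:
                    ac, an, sc = _counts_from_genotypes(variant, alt_index)
                if ac is not None and ac == 0:
                    logger.warning(
                        "skipping ALT with zero observed copies at %s:%s in %s",
                        variant.chrom,
                        variant.pos,
                        path,
                    )
                    continue
                _merge_record(
                    index,
                    ObservationRecord(
                        key=key,
                        allele_count=ac,
                        call_count=an,
                        sample_count=sc,
                        extra_metadata=dict(extra),
                    ),
                )
    return index


# ---------------------------------------------------------------------------
# Index persistence: a versioned single-file JSON serialization.
# ---------------------------------------------------------------------------


def save_index(index: DatasetIndex, path) -> None:
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "dataset_id": index.dataset_id,
        "assembly_id": index.assembly_id,
        "sample_total": index.sample_total,
        "source_path": index.source_path,
        "records": [
            {
                "chromosome": k.chromosome,
                "start": k.start,
                "ref": k.ref_bases,
                "alt": k.alt_bases,
                "allele_count": r.allele_count,
                "call_count": r.call_count,
                "sample_count": r.sample_count,
                "extra_metadata": r.extra_metadata,
            }
            for k, r in index.records.items()
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_index(path) -> DatasetIndex:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise IngestError(f"unsupported index format version {version!r} in {path}")
    index = DatasetIndex(
        dataset_id=payload["dataset_id"],
        assembly_id=payload["assembly_id"],
        sample_total=payload.get("sample_total"),
        source_path=payload.get("source_path", ""),
    )
    for rec in payload["records"]:
        key = AlleleKey(
            assembly_id=index.assembly_id,
            chromosome=rec["chromosome"],
            start=int(rec["start"]),
            ref_bases=rec["ref"],
            alt_bases=rec["alt"],
        )
        index.records[key] = ObservationRecord(
            key=key,
            allele_count=rec.get("allele_count"),
            call_count=rec.get("call_count"),
            sample_count=rec.get("sample_count"),
            extra_metadata=dict(rec.get("extra_metadata") or {}),
        )
    return index
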