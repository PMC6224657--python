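"""Variant-level computations: VAF filtering, clonality calls, CCF, HGVS-p parsing.

A somatic variant detected in bulk blood at variant allele frequency (VAF) v
marks a clone of roughly 2v of nucleated cells when heterozygous and diploid.
This module implements the standard per-variant operations: the VAF
retention filter, clonal/subclonal classification at a VAF threshold,
summary statistics, conversion to cancer cell fraction (CCF) with purity and
copy-number adjustment, consequence classification from HGVS-p style protein
changes, and a lymphoid/non-lymphoid lineage-concordance call.
"""

from __future__ import annotations

import math
import re
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "VariantRecord",
    "CcfInput",
    "CcfResult",
    "LineagePair",
    "VafSummary",
    "filter_vaf",
    "classify_clonal",
    "vaf_summary",
    "compute_ccf",
    "classify_consequence",
    "lineage_concordance",
    "PPM1D_EXON_RANGES",
]

CONSEQUENCES = ("nonsense", "frameshift", "missense", "other", "unparsed")

#: Provisional residue-range -> exon map for PPM1D (605 aa); exon boundaries
#: are approximate and user-replaceable. Exon 6 carries the C-terminal
#: truncating mutations characteristic of clonal hematopoiesis.
PPM1D_EXON_RANGES: tuple[tuple[int, int, int], ...] = (
    (1, 99, 1),
    (100, 170, 2),
    (171, 270, 3),
    (271, 330, 4),
    (331, 420, 5),
    (421, 605, 6),
)


@dataclass
class VariantRecord:
    """One somatic call: sample, gene, protein change, consequence, VAF."""

    sample_id: str
    gene: str
    protein_change: str
    consequence: str
    vaf: float
    exon: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"consequence must be one of {CONSEQUENCES}, got {self.consequence!r}"
            )


@dataclass(frozen=True)
class CcfInput:
    """Inputs for the cancer-cell-fraction conversion.

    Defaults describe a heterozygous point mutation at a diploid locus in a
    pure sample: purity 1.0, tumor and normal copy number 2, multiplicity 1.
    """

    vaf: float
    purity: float = 1.0
    cn_tumor: int = 2
    cn_normal: int = 2
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.cn_tumor < 1:
            raise ValueError(f"cn_tumor must be >= 1, got {self.cn_tumor}")
        if self.cn_normal < 0:
            raise ValueError(f"cn_normal must be >= 0, got {self.cn_normal}")
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")


@dataclass(frozen=True)
class CcfResult:
    ccf: float
    raw: float
    clamped: bool


@dataclass(frozen=True)
class LineagePair:
    """VAF of one variant in sorted lymphoid vs non-lymphoid blood fractions."""

    sample_id: str
    vaf_lymphoid: float
    vaf_nonlymphoid: float
    lod: float = 0.02

    def __post_init__(self) -> None:
        for name in ("vaf_lymphoid", "vaf_nonlymphoid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lod <= 0:
            raise ValueError(f"lod must be > 0, got {self.lod}")


@dataclass(frozen=True)
class VafSummary:
    n: int
    mean: float
    median: float
    min: float
    max: float


def filter_vaf(
    records: Sequence[VariantRecord], min_vaf: float = 0.02
) -> tuple[list[VariantRecord], int]:
    """Retain variants with VAF >= min_vaf (inclusive bound), preserving order.

    Returns (retained, n_removed).  The default 0.02 is the conventional
    detection floor for targeted sequencing of clonal hematopoiesis.
    """
    if not 0.0 <= min_vaf <= 1.0:
        raise ValueError(f"min_vaf must be in [0, 1], got {min_vaf}")
    kept = [rec for rec in records if rec.vaf >= min_vaf]
    return kept, len(records) - len(kept)


def classify_clonal(record: VariantRecord | float, threshold: float = 0.2) -> str:
    """'clonal' iff VAF strictly exceeds the threshold, else 'subclonal'."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    vaf = record.vaf if isinstance(record, VariantRecord) else float(record)
    return "clonal" if vaf > threshold else "subclonal"


def vaf_summary(records: Sequence[VariantRecord]) -> VafSummary:
    """n/mean/median/min/max of the VAFs (median = midpoint for even n)."""
    if not records:
        raise ValueError("cannot summarize an empty variant list")
    vafs = [rec.vaf for rec in records]
    return VafSummary(
        n=len(vafs),
        mean=statistics.fmean(vafs),
        median=statistics.median(vafs),
        min=min(vafs),
        max=max(vafs),
    )


def compute_ccf(x: CcfInput) -> CcfResult:
    """Cancer cell fraction from VAF with purity/copy-number adjustment.

    CCF = vaf * (purity * cn_tumor + (1 - purity) * cn_normal)
          / (purity * multiplicity),
    clamped to [0, 1].  The ``clamped`` flag is set when the raw value
    exceeds 1.05, i.e. when the inputs are inconsistent with a clonal
    heterozygous event rather than merely at the clonal boundary.
    With the defaults (pure diploid heterozygous) this reduces to 2 * vaf.
    """
    raw = (
        x.vaf
        * (x.purity * x.cn_tumor + (1.0 - x.purity) * x.cn_normal)
        / (x.purity * x.multiplicity)
    )
    return CcfResult(ccf=min(max(raw, 0.0), 1.0), raw=raw, clamped=raw > 1.05)


_NONSENSE_RE = re.compile(r"^([A-Z])(\d+)(?:X|\*|Ter)$")
_FRAMESHIFT_RE = re.compile(r"^([A-Z])(\d+)(?:[A-Z][a-z]{0,2})?fs(?:\*?\d+|Ter\d*)?$")
_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-WYZ])$")
_OTHER_RE = re.compile(r"^([A-Z])(\d+)(?:=|del|dup|ins[A-Z]*)$")


def classify_consequence(
    protein_change: str,
    exon_map: Iterable[tuple[int, int, int]] | None = None,
) -> tuple[str, int | None, bool]:
    """Classify an HGVS-p style protein change.

    Accepts bare ("R458X") and "p."-prefixed ("p.L450fs") forms and both "X"
    and "*" stop notations.  Returns (consequence, exon, truncating) where
    truncating means nonsense or frameshift, and exon is looked up from the
    optional residue-range map [(start, end, exon), ...].  Strings that are
    not protein notation (e.g. "c.100del") come back as ('unparsed', None,
    False) rather than raising.
    """
    if not protein_change:
        raise ValueError("protein_change must be non-empty")
    s = protein_change.strip()
    if s.lower().startswith("p."):
        s = s[2:]

    consequence, residue = "unparsed", None
    if m := _NONSENSE_RE.match(s):
        consequence, residue = "nonsense", int(m.group(2))
    elif m := _FRAMESHIFT_RE.match(s):
        consequence, residue = "frameshift", int(m.group(2))
    elif m := _MISSENSE_RE.match(s):
        consequence, residue = "missense", int(m.group(2))
    elif m := _OTHER_RE.match(s):
        consequence, residue = "other", int(m.group(2))

    exon = None
    if residue is not None and exon_map is not None:
        for start, end, ex in exon_map:
            if start <= residue <= end:
                exon = ex
                break
    return consequence, exon, consequence in ("nonsense", "frameshift")


def lineage_concordance(pair: LineagePair) -> str:
    """Call a variant multilineage / lineage_restricted / undetected.

    Detection of the same variant in both lymphoid and non-lymphoid sorted
    fractions (both VAFs at or above the limit of detection) indicates an
    origin in a stem or early progenitor cell.
    """
    in_lymph = pair.vaf_lymphoid >= pair.lod
    in_nonlymph = pair.vaf_nonlymphoid >= pair.lod
    if in_lymph and in_nonlymph:
        return "multilineage"
    if in_lymph or in_nonlymph:
        return "lineage_restricted"
    return "undetected"
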