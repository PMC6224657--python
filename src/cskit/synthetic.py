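"""Synthetic cohorts, variant tables, and competition/chimerism trajectories.

Everything downstream of sequencing is testable without patient data:
this module plants known ground truth — per-(exposure, gene) log odds
ratios, pairwise gene co-occurrence log-ORs, a scaled-Beta VAF
distribution, and per-dose differential survival — and generates tables in
the same shapes the analysis operations consume.

Randomness uses one root seed per spec with ``numpy.random.SeedSequence``
stream-splitting, so replicate k of a run is individually reproducible and
outputs are byte-identical across reruns of the same spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clonality import VariantRecord
from .selection import CompetitionSpec, Trajectory, simulate_competition

__all__ = [
    "CohortSpec",
    "CompetitionSpec",
    "DEFAULT_VAF_SHAPE",
    "generate_cohort",
    "generate_competition",
    "generate_chimerism",
    "variants_to_frame",
]

#: Scaled-Beta shape parameters on [0.02, 0.47] matched to the observed VAF
#: summary of therapy-related myeloid cohorts: mean 0.11, median 0.05.
DEFAULT_VAF_SHAPE: tuple[float, float] = (0.262, 1.048)

CASE_LABEL = "t-MN"
CONTROL_LABEL = "de novo"


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with planted exposure and co-occurrence effects.

    Per-gene mutation probability starts at ``base_rate`` (on the logit
    scale) and is shifted additively by ``effect_log_or[(exposure, gene)]``
    for each positive exposure flag and by ``cooccur_log_or[(g1, g2)]``
    for each already-mutated earlier gene (genes are drawn in list order).
    Each mutated (sample, gene) yields one variant with VAF drawn from a
    Beta(``vaf_shape``) rescaled to [vaf_min, vaf_max].
    """

    n_case: int = 156
    n_control: int = 228
    genes: tuple[str, ...] = ("PPM1D", "TP53", "TET2", "DNMT3A")
    base_rate: float = 0.1
    exposures: Mapping[str, float] = field(
        default_factory=lambda: {"cisplatin": 0.3, "etoposide": 0.25, "vincristine": 0.2}
    )
    effect_log_or: Mapping[tuple[str, str], float] = field(default_factory=dict)
    cooccur_log_or: Mapping[tuple[str, str], float] = field(default_factory=dict)
    vaf_shape: tuple[float, float] = DEFAULT_VAF_SHAPE
    vaf_min: float = 0.02
    vaf_max: float = 0.47
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1:
            raise ValueError(f"n_case must be >= 1, got {self.n_case}")
        if self.n_control < 1:
            raise ValueError(f"n_control must be >= 1, got {self.n_control}")
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError(f"base_rate must be in [0, 1], got {self.base_rate}")
        for name, prev in dict(self.exposures).items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"exposures[{name!r}] must be in [0, 1], got {prev}")
        if not 0.0 <= self.vaf_min < self.vaf_max <= 1.0:
            raise ValueError(
                f"need 0 <= vaf_min < vaf_max <= 1, got vaf_min={self.vaf_min}, vaf_max={self.vaf_max}"
            )
        if self.vaf_shape[0] <= 0 or self.vaf_shape[1] <= 0:
            raise ValueError(f"vaf_shape parameters must be > 0, got {self.vaf_shape}")
        object.__setattr__(self, "genes", tuple(self.genes))


def _mutation_logit(
    spec: CohortSpec,
    gene: str,
    exposure_flags: Mapping[str, int],
    earlier_flags: Mapping[str, int],
) -> float:
    base = logit(min(max(spec.base_rate, 1e-12), 1 - 1e-12))
    shift = sum(
        eff * exposure_flags[exp]
        for (exp, g), eff in dict(spec.effect_log_or).items()
        if g == gene and exp in exposure_flags
    )
    for (g1, g2), eff in dict(spec.cooccur_log_or).items():
        if g2 == gene and earlier_flags.get(g1):
            shift += eff
        elif g1 == gene and earlier_flags.get(g2):
            shift += eff
    return float(base + shift)


def _draw_protein_change(rng: np.random.Generator) -> tuple[str, str]:
    """A synthetic truncating protein change in the exon-6-like range."""
    residue = int(rng.integers(421, 606))
    aa = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
    if rng.random() < 0.5:
        return f"p.{aa}{residue}X", "nonsense"
    return f"p.{aa}{residue}fs", "frameshift"


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[VariantRecord]]:
    """Generate (cohort table, variant list) with planted ground truth.

    The cohort table has one row per sample: sample_id, group, one 0/1
    column per exposure, one 0/1 column per gene.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_case + spec.n_control
    groups = [CASE_LABEL] * spec.n_case + [CONTROL_LABEL] * spec.n_control
    sample_ids = [f"S{i:05d}" for i in range(n)]
    exposures = dict(spec.exposures)

    rows: list[dict] = []
    variants: list[VariantRecord] = []
    lo, hi = spec.vaf_min, spec.vaf_max
    a_shape, b_shape = spec.vaf_shape
    for sid, group in zip(sample_ids, groups):
        row: dict = {"sample_id": sid, "group": group}
        for exp, prev in exposures.items():
            row[exp] = int(rng.random() < prev)
        flags: dict[str, int] = {}
        for gene in spec.genes:
            p = expit(_mutation_logit(spec, gene, row, flags))
            flag = int(rng.random() < p)
            flags[gene] = flag
            row[gene] = flag
            if flag:
                vaf = float(lo + (hi - lo) * rng.beta(a_shape, b_shape))
                protein_change, consequence = _draw_protein_change(rng)
                variants.append(
                    VariantRecord(
                        sample_id=sid, gene=gene, protein_change=protein_change,
                        consequence=consequence, vaf=vaf,
                    )
                )
        rows.append(row)

    cohort = pd.DataFrame(rows)
    return cohort, variants


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Variant list as a MAF-like table (one row per call)."""
    return pd.DataFrame(
        [
            {
                "sample_id": v.sample_id,
                "gene": v.gene,
                "protein_change": v.protein_change,
                "consequence": v.consequence,
                "vaf": v.vaf,
            }
            for v in variants
        ],
        columns=["sample_id", "gene", "protein_change", "consequence", "vaf"],
    )


def _replicate_rngs(spec: CompetitionSpec) -> list[np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    return [np.random.default_rng(c) for c in children]


def generate_competition(spec: CompetitionSpec) -> list[Trajectory]:
    """Simulate ``spec.replicates`` independent competition trajectories.

    Each replicate runs the per-dose survival simulator on its own spawned
    random stream; ground-truth parameters ride in each trajectory's meta.
    Measure days beyond the simulated horizon raise.
    """
    trajectories = []
    for i, rng in enumerate(_replicate_rngs(spec)):
        traj = simulate_competition(spec, rng)
        traj.meta["replicate"] = i
        trajectories.append(traj)
    return trajectories


def generate_chimerism(spec: CompetitionSpec, engraft_frac: float = 1.0) -> list[Trajectory]:
    """Competition trajectories behind a transplant engraftment bottleneck.

    Before dosing, each clone's initial pool is thinned independently by a
    binomial draw with success probability ``engraft_frac``, modeling the
    loss of transplanted cells that fail to engraft; the measured baseline
    fraction therefore scatters around f0 with extra variance.  With
    ``engraft_frac == 1`` this is exactly ``generate_competition``.
    """
    if not 0.0 < engraft_frac <= 1.0:
        raise ValueError(f"engraft_frac must be in (0, 1], got {engraft_frac}")
    if engraft_frac == 1.0:
        return generate_competition(spec)
    n_mut_seed = int(round(spec.f0 * spec.n0))
    n_wt_seed = spec.n0 - n_mut_seed
    trajectories = []
    for i, rng in enumerate(_replicate_rngs(spec)):
        n_mut0 = int(rng.binomial(n_mut_seed, engraft_frac))
        n_wt0 = int(rng.binomial(n_wt_seed, engraft_frac))
        traj = simulate_competition(spec, rng, n_mut0=n_mut0, n_wt0=n_wt0)
        traj.meta["replicate"] = i
        traj.meta["engraft_frac"] = engraft_frac
        trajectories.append(traj)
    return trajectories


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Trajectory list as a tidy table (replicate, day, mutant_count, total_count)."""
    records: list[dict] = []
    for i, traj in enumerate(trajectories):
        rep = traj.meta.get("replicate", i)
        records.extend(traj.to_records(replicate=rep))
    return pd.DataFrame(
        records, columns=["replicate", "day", "mutant_count", "total_count"]
    )


__all__.append("trajectories_to_frame")
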