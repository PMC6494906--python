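"""Pairwise-distance "organizational layout" of the subunit panel.

For one profile of panel values the individual vector holds, for each of
the 171 canonical gene pairs (x, y), the absolute difference |x - y|. The
consensus vector over n subjects holds, per pair, the root of the summed
squared per-subject differences (no normalization by n; the stereotypy
correlation is scale-invariant, so none is needed). Stereotypy is the
Pearson correlation between an individual vector and a consensus vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Dendrogram, ward_from_distance_vector
from .expression_io import ExpressionMatrix
from .ontology import OntologyMap
from .panel import GenePanel

__all__ = [
    "DistanceVector",
    "StereotypyReport",
    "pair_distance_individual",
    "pair_distance_consensus",
    "stereotypy",
    "whole_brain_profiles",
    "reference_similarity",
    "layout_dendrogram",
    "compare_to_reference",
    "DunnettResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceVector:
    """Ordered pairwise distances for one profile or a consensus."""

    panel: GenePanel
    values: Tuple[float, ...]
    kind: str  # {individual, consensus}
    context: Tuple[str, str, str] = ("", "whole_brain", "log2")

    def __post_init__(self) -> None:
        n = len(self.panel)
        expect = n * (n - 1) // 2
        if len(self.values) != expect:
            raise ValueError(f"expected {expect} pair distances, got {len(self.values)}")
        if any(v < 0 for v in self.values):
            raise ValueError("pair distances must be nonnegative")
        if self.kind not in ("individual", "consensus"):
            raise ValueError(f"invalid kind {self.kind!r}")

    @property
    def pair_order(self) -> List[Tuple[str, str]]:
        return self.panel.pair_order

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _profile_vector(profile: Dict[str, float], panel: GenePanel) -> np.ndarray:
    missing = [g for g in panel.symbols if g not in profile]
    if missing:
        raise KeyError(f"profile missing genes: {missing}")
    vec = np.array([float(profile[g]) for g in panel.symbols])
    if not np.all(np.isfinite(vec)):
        raise ValueError("profile contains non-finite values")
    return vec


def pair_distance_individual(
    profile: Dict[str, float],
    panel: GenePanel,
    context: Tuple[str, str, str] = ("", "whole_brain", "log2"),
) -> DistanceVector:
    """|x - y| over the canonical pair order, for one subject profile."""
    vec = _profile_vector(profile, panel)
    i, j = np.triu_indices(len(vec), k=1)
    return DistanceVector(
        panel=panel,
        values=tuple(np.abs(vec[i] - vec[j])),
        kind="individual",
        context=context,
    )


def pair_distance_consensus(
    profiles: Sequence[Dict[str, float]],
    panel: GenePanel,
    context: Tuple[str, str, str] = ("consensus", "whole_brain", "log2"),
) -> DistanceVector:
    """Root of summed squared per-subject pair differences.

    With a single subject this reduces exactly to the individual vector.
    """
    if not profiles:
        raise ValueError("need at least one subject profile")
    vecs = np.stack([_profile_vector(p, panel) for p in profiles])
    i, j = np.triu_indices(vecs.shape[1], k=1)
    diffs = vecs[:, i] - vecs[:, j]  # (subjects, pairs)
    return DistanceVector(
        panel=panel,
        values=tuple(np.sqrt((diffs**2).sum(axis=0))),
        kind="consensus",
        context=context,
    )


def stereotypy(individual: DistanceVector, consensus: DistanceVector) -> float:
    """Pearson correlation between the two distance vectors."""
    if individual.panel.symbols != consensus.panel.symbols:
        raise ValueError("distance vectors use different panels")
    x = individual.as_array()
    y = consensus.as_array()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance distance vector; stereotypy undefined")
    return float(np.corrcoef(x, y)[0, 1])


def whole_brain_profiles(
    subject_matrices: Sequence[ExpressionMatrix], panel: GenePanel
) -> List[Dict[str, float]]:
    """Per-subject whole-brain profile: each gene's mean over substructures."""
    out = []
    for m in subject_matrices:
        out.append({g: float(m.row(g).mean()) for g in panel.symbols if g in m.row_ids})
    return out


@dataclass(frozen=True)
class StereotypyRow:
    subject: str
    substructure: str
    structure: str
    r: float


class StereotypyReport:
    """R(d_i, d_c,ref) per subject and substructure, rostro-caudally ordered."""

    def __init__(
        self,
        rows: Sequence[StereotypyRow],
        reference: str,
        transform: str = "log2",
    ):
        for row in rows:
            if not -1.0 - 1e-9 <= row.r <= 1.0 + 1e-9:
                raise ValueError(f"R out of [-1, 1]: {row.r}")
        self.rows = list(rows)
        self.reference = reference
        self.transform = transform

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": r.subject,
                    "substructure": r.substructure,
                    "structure": r.structure,
                    "transform": self.transform,
                    "R": r.r,
                }
                for r in self.rows
            ]
        )

    def mean_r(self, substructures: Optional[Sequence[str]] = None) -> float:
        rs = [
            r.r
            for r in self.rows
            if substructures is None or r.substructure in substructures
        ]
        if not rs:
            raise ValueError("no matching rows")
        return float(np.mean(rs))

    def mean_r_by_substructure(self) -> Dict[str, float]:
        acc: Dict[str, List[float]] = {}
        for r in self.rows:
            acc.setdefault(r.substructure, []).append(r.r)
        return {k: float(np.mean(v)) for k, v in acc.items()}


def reference_similarity(
    subject_matrices: Sequence[ExpressionMatrix],
    panel: GenePanel,
    ontology: OntologyMap,
    reference: str,
    transform: str = "log2",
) -> StereotypyReport:
    """Stereotypy of every (subject, substructure) against the reference
    substructure's cross-subject consensus vector.

    ``subject_matrices`` are substructure-aggregated, one per subject, with
    the panel genes as rows.
    """
    ref_profiles = []
    for m in subject_matrices:
        if reference not in m.sample_ids:
            subj = m.samples[0].subject_id if m.samples else "?"
            raise ValueError(
                f"reference substructure {reference!r} missing for subject {subj!r}"
            )
        col = m.sample_ids.index(reference)
        ref_profiles.append(
            {g: float(m.values[m.row_ids.index(g), col]) for g in panel.symbols}
        )
    d_ref = pair_distance_consensus(
        ref_profiles, panel, context=("consensus", reference, transform)
    )

    rows = []
    for m in subject_matrices:
        subject = m.samples[0].subject_id
        for col, rec in enumerate(m.samples):
            profile = {
                g: float(m.values[m.row_ids.index(g), col]) for g in panel.symbols
            }
            d_i = pair_distance_individual(
                profile, panel, context=(subject, rec.substructure, transform)
            )
            rows.append(
                StereotypyRow(
                    subject=subject,
                    substructure=rec.substructure,
                    structure=ontology[rec.substructure].structure
                    if rec.substructure in ontology
                    else "",
                    r=stereotypy(d_i, d_ref),
                )
            )
    rank = {c: k for k, c in enumerate(ontology.substructures)}
    rows.sort(key=lambda r: (rank.get(r.substructure, len(rank)), r.subject))
    return StereotypyReport(rows, reference=reference, transform=transform)


def layout_dendrogram(d: DistanceVector) -> Dendrogram:
    """Ward clustering of the panel genes using the pair distances as the
    base dissimilarity."""
    return ward_from_distance_vector(
        d.as_array(), labels=list(d.panel.symbols)
    )


# ---------------------------------------------------------------------------
# ANOVA + Dunnett


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    anova_p: float
    reference_group: str
    contrasts: Dict[str, Tuple[float, float]]  # group -> (t, adjusted p)
    excluded_groups: Tuple[str, ...] = ()

    def significant(self, alpha: float = 0.05) -> List[str]:
        return [g for g, (_, p) in self.contrasts.items() if p < alpha]


def compare_to_reference(
    report: StereotypyReport,
    reference_group: str,
    grouping: str = "structure",
    n_sim: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """One-way ANOVA across groups of R values plus Dunnett-style
    many-to-one contrasts against the reference group.

    Adjusted p values come from a seeded simulation of the max-|t| null:
    per draw, group means are sampled from their standard-error normals, a
    pooled variance is drawn from the chi-square reference distribution,
    and each contrast's |t| is compared against the simulated maximum.
    Groups with fewer than 2 observations are excluded with a warning.
    """
    frame = report.to_frame()
    if grouping not in frame.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    groups: Dict[str, np.ndarray] = {
        name: sub["R"].to_numpy(dtype=float)
        for name, sub in frame.groupby(grouping, sort=False)
    }
    excluded = tuple(sorted(g for g, v in groups.items() if len(v) < 2))
    if excluded:
        warnings.warn(f"excluding single-observation groups: {excluded}")
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not available")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for the comparison")

    names = list(groups)
    values = [groups[g] for g in names]
    f_stat, anova_p = stats.f_oneway(*values)

    ref = groups[reference_group]
    others = [g for g in names if g != reference_group]
    n_total = sum(len(v) for v in values)
    df = n_total - len(names)
    pooled = sum(((len(v) - 1) * v.var(ddof=1) for v in values)) / df
    if pooled <= 0:
        # all groups internally constant: contrasts are exact
        contrasts = {
            g: (np.inf if groups[g].mean() != ref.mean() else 0.0,
                0.0 if groups[g].mean() != ref.mean() else 1.0)
            for g in others
        }
        return DunnettResult(
            float(f_stat), float(anova_p), reference_group, contrasts, excluded
        )

    t_obs = {}
    for g in others:
        se = np.sqrt(pooled * (1.0 / len(groups[g]) + 1.0 / len(ref)))
        t_obs[g] = float((groups[g].mean() - ref.mean()) / se)

    rng = np.random.default_rng(seed)
    k = len(others)
    z_other = rng.standard_normal((n_sim, k)) / np.sqrt(
        np.array([len(groups[g]) for g in others])
    )
    z_ref = rng.standard_normal((n_sim, 1)) / np.sqrt(len(ref))
    s2 = rng.chisquare(df, size=(n_sim, 1)) / df
    se_sim = np.sqrt(
        s2 * (1.0 / np.array([len(groups[g]) for g in others]) + 1.0 / len(ref))
    )
    t_sim = (z_other - z_ref) / se_sim
    max_abs = np.abs(t_sim).max(axis=1)
    contrasts = {
        g: (t_obs[g], float((max_abs >= abs(t_obs[g])).mean())) for g in others
    }
    return DunnettResult(
        float(f_stat), float(anova_p), reference_group, contrasts, excluded
    )
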