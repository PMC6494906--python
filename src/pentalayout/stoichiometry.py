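"""Family sums, 2:2:1 stoichiometric gating, sampling-convergence curves,
pairwise correlation reports, and the cross-level consensus pair table."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenePanel
from .preprocess import CompositionMatrix

__all__ = [
    "NucleusProfile",
    "GateWindows",
    "CorrelationReport",
    "PairCorrelation",
    "ConsensusPairTable",
    "ConsensusPairRow",
    "family_sums",
    "profiles_from_composition",
    "stoichiometric_gate",
    "convergence_curve",
    "pairwise_correlations",
    "consensus_pairs",
]

log = logging.getLogger(__name__)

#: the 11 genes carrying ~95% of the panel-wide signal, used for the
#: correlation analyses
HIGH_EXPRESSION_GENES = (
    "GABRA1", "GABRA2", "GABRA3", "GABRA4", "GABRA5",
    "GABRB1", "GABRB2", "GABRB3",
    "GABRG1", "GABRG2", "GABRD",
)


@dataclass(frozen=True)
class NucleusProfile:
    """One nucleus: its panel composition and the three stoichiometric sums."""

    nucleus_id: str
    composition: Tuple[float, ...]
    sigma_alpha: float
    sigma_beta: float
    sigma_chi: float
    cell_type: str = ""
    cell_class: str = ""


def family_sums(composition: Sequence[float], panel: GenePanel) -> Tuple[float, float, float]:
    """(Sigma-alpha, Sigma-beta, Sigma-chi) for one composition column.

    Genes tagged ``excluded`` (the rho genes on the default panel) count in
    none of the sums, so the three sums total 100 minus the excluded mass.
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (len(panel),):
        raise ValueError(f"composition length {comp.shape} != panel size {len(panel)}")
    sums = {"SigmaAlpha": 0.0, "SigmaBeta": 0.0, "SigmaChi": 0.0, "excluded": 0.0}
    for value, sym in zip(comp, panel.symbols):
        sums[panel.sum_membership[sym]] += float(value)
    return sums["SigmaAlpha"], sums["SigmaBeta"], sums["SigmaChi"]


def profiles_from_composition(comp: CompositionMatrix) -> List[NucleusProfile]:
    """Wrap each composition column as a NucleusProfile with its sums."""
    out = []
    for j, rec in enumerate(comp.samples):
        col = comp.values[:, j]
        a, b, c = family_sums(col, comp.panel)
        out.append(
            NucleusProfile(
                nucleus_id=rec.sample_id,
                composition=tuple(col),
                sigma_alpha=a,
                sigma_beta=b,
                sigma_chi=c,
                cell_type=rec.cell_type,
                cell_class=rec.cell_class,
            )
        )
    return out


@dataclass(frozen=True)
class GateWindows:
    """Closed acceptance windows (center, half-width) for the three sums."""

    alpha: Tuple[float, float] = (40.0, 5.0)
    beta: Tuple[float, float] = (40.0, 5.0)
    chi: Tuple[float, float] = (20.0, 5.0)

    def __post_init__(self) -> None:
        for center, half in (self.alpha, self.beta, self.chi):
            if half < 0:
                raise ValueError("window half-width must be >= 0")
            if center - half < 0 or center + half > 100:
                raise ValueError(
                    f"window {center}+/-{half} exceeds the [0, 100] range"
                )

    def contains(self, a: float, b: float, c: float) -> bool:
        return (
            abs(a - self.alpha[0]) <= self.alpha[1]
            and abs(b - self.beta[0]) <= self.beta[1]
            and abs(c - self.chi[0]) <= self.chi[1]
        )


def stoichiometric_gate(
    nuclei: Sequence[NucleusProfile], windows: GateWindows = GateWindows()
) -> Tuple[List[NucleusProfile], Dict[str, Dict[str, int]]]:
    """Keep nuclei whose three sums all fall inside the closed windows.

    Returns the filtered list plus kept/dropped counts per cell type.
    """
    kept: List[NucleusProfile] = []
    counts: Dict[str, Dict[str, int]] = {}
    for nuc in nuclei:
        tally = counts.setdefault(nuc.cell_type, {"kept": 0, "dropped": 0})
        if windows.contains(nuc.sigma_alpha, nuc.sigma_beta, nuc.sigma_chi):
            kept.append(nuc)
            tally["kept"] += 1
        else:
            tally["dropped"] += 1
    return kept, counts


def convergence_curve(
    nuclei: Sequence[NucleusProfile],
    sample_sizes: Sequence[int],
    n_draws: int,
    seed: int,
) -> pd.DataFrame:
    """Subsampling convergence of the three sums toward their means.

    For each size, ``n_draws`` subsamples without replacement; reports the
    mean-of-means and the SD of subsample means per sum.
    """
    rng = np.random.default_rng(seed)
    sums = np.array([(n.sigma_alpha, n.sigma_beta, n.sigma_chi) for n in nuclei])
    pop = len(nuclei)
    rows = []
    for size in sample_sizes:
        if size > pop:
            raise ValueError(f"sample size {size} exceeds population {pop}")
        means = np.empty((n_draws, 3))
        for d in range(n_draws):
            idx = rng.choice(pop, size=size, replace=False)
            means[d] = sums[idx].mean(axis=0)
        mu = means.mean(axis=0)
        sd = means.std(axis=0, ddof=0)
        rows.append(
            {
                "size": size,
                "mean_alpha": mu[0], "mean_beta": mu[1], "mean_chi": mu[2],
                "sd_alpha": sd[0], "sd_beta": sd[1], "sd_chi": sd[2],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairCorrelation:
    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError(f"r out of [-1, 1]: {self.r}")
        if self.n < 3:
            raise ValueError("correlations need n >= 3")


@dataclass(frozen=True)
class CorrelationReport:
    """All unordered pairwise Pearson correlations at one analysis level.

    ``tag`` identifies the level: A (across substructures), B (across
    samples), C (across cell-type means), D (within one cell type).
    """

    tag: str
    unit: str
    pairs: Tuple[PairCorrelation, ...]
    cell_type: str = ""
    cell_class: str = ""
    skipped: Tuple[str, ...] = ()

    def lookup(self, gene_a: str, gene_b: str) -> Optional[PairCorrelation]:
        a, b = sorted((gene_a, gene_b))
        for p in self.pairs:
            if sorted((p.gene_a, p.gene_b)) == [a, b]:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tag": self.tag, "gene_a": p.gene_a, "gene_b": p.gene_b,
                    "r": p.r, "p": p.p, "n": p.n,
                    "cell_type": self.cell_type, "cell_class": self.cell_class,
                }
                for p in self.pairs
            ]
        )


def pairwise_correlations(
    observations: pd.DataFrame,
    gene_subset: Sequence[str] = HIGH_EXPRESSION_GENES,
    tag: str = "A",
    unit: str = "substructures",
    cell_type: str = "",
    cell_class: str = "",
) -> CorrelationReport:
    """Pearson r and two-tailed p for every unordered pair in the subset.

    ``observations`` is an observations x genes table. Zero-variance genes
    are skipped and flagged on the report.
    """
    genes = [g for g in gene_subset if g in observations.columns]
    missing = set(gene_subset) - set(genes)
    if missing:
        raise KeyError(f"genes absent from observations: {sorted(missing)}")
    n = len(observations)
    if n < 3:
        raise ValueError(f"need >= 3 observations, got {n}")
    skipped = []
    pairs = []
    for a, b in combinations(genes, 2):
        x = observations[a].to_numpy(dtype=float)
        y = observations[b].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            skipped.append(f"{a}-{b}")
            continue
        r, p = stats.pearsonr(x, y)
        pairs.append(PairCorrelation(a, b, float(r), float(p), n))
    if skipped:
        log.info("skipped %d zero-variance pairs in report %s", len(skipped), tag)
    return CorrelationReport(
        tag=tag,
        unit=unit,
        pairs=tuple(pairs),
        cell_type=cell_type,
        cell_class=cell_class,
        skipped=tuple(skipped),
    )


@dataclass(frozen=True)
class ConsensusPairRow:
    gene_a: str
    gene_b: str
    direction: str  # {positive, negative, both}
    supporting_datasets: Tuple[str, ...]
    supporting_cell_types: Tuple[str, ...] = ()
    supporting_cell_classes: Tuple[str, ...] = ()


class ConsensusPairTable:
    def __init__(self, rows: Sequence[ConsensusPairRow], alpha: float, min_support: int):
        self.rows = list(rows)
        self.alpha = alpha
        self.min_support = min_support

    def direction_of(self, gene_a: str, gene_b: str) -> Optional[str]:
        key = tuple(sorted((gene_a, gene_b)))
        dirs = {
            r.direction
            for r in self.rows
            if tuple(sorted((r.gene_a, r.gene_b))) == key
        }
        if not dirs:
            return None
        if dirs == {"positive"} or dirs == {"negative"}:
            return dirs.pop()
        return "both"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": r.gene_a, "gene_b": r.gene_b,
                    "direction": r.direction,
                    "datasets": ",".join(r.supporting_datasets),
                    "cell_types": ",".join(r.supporting_cell_types),
                    "cell_classes": ",".join(r.supporting_cell_classes),
                }
                for r in self.rows
            ]
        )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


def consensus_pairs(
    reports: Sequence[CorrelationReport],
    alpha: float = 0.05,
    min_support: int = 2,
    bh_correct: bool = False,
) -> ConsensusPairTable:
    """Cross-level consensus: a pair enters with a direction when it is
    significant with that sign in at least ``min_support`` reports.

    Within-cell-type reports (tag D) sharing the tag count as one dataset
    but contribute their cell types/classes to the support columns. Pairs
    significant with opposite signs in different analyses appear under
    both directions (flagged via :meth:`ConsensusPairTable.direction_of`).
    """
    if len(reports) < 2:
        raise ValueError("consensus needs at least 2 reports")
    support: Dict[Tuple[str, str], Dict[str, Dict[str, set]]] = {}
    n_reports: Dict[Tuple[str, str], Dict[str, int]] = {}
    for rep in reports:
        pvals = np.array([p.p for p in rep.pairs])
        effective = _bh_adjust(pvals) if (bh_correct and len(pvals)) else pvals
        for pc, p_eff in zip(rep.pairs, effective):
            if p_eff >= alpha or pc.r == 0:
                continue
            key = tuple(sorted((pc.gene_a, pc.gene_b)))
            sign = "positive" if pc.r > 0 else "negative"
            slot = support.setdefault(
                key,
                {
                    s: {"datasets": set(), "types": set(), "classes": set()}
                    for s in ("positive", "negative")
                },
            )[sign]
            counts = n_reports.setdefault(key, {"positive": 0, "negative": 0})
            counts[sign] += 1
            slot["datasets"].add(rep.tag)
            if rep.cell_type:
                slot["types"].add(rep.cell_type)
            if rep.cell_class:
                slot["classes"].add(rep.cell_class)
    rows = []
    for (a, b), per_sign in sorted(support.items()):
        qualified = [
            sign
            for sign in ("positive", "negative")
            if n_reports[(a, b)][sign] >= min_support
        ]
        if not qualified:
            continue
        if len(qualified) == 2:
            rows.append(
                ConsensusPairRow(
                    gene_a=a,
                    gene_b=b,
                    direction="both",
                    supporting_datasets=tuple(
                        sorted(
                            per_sign["positive"]["datasets"]
                            | per_sign["negative"]["datasets"]
                        )
                    ),
                    supporting_cell_types=tuple(
                        sorted(per_sign["positive"]["types"] | per_sign["negative"]["types"])
                    ),
                    supporting_cell_classes=tuple(
                        sorted(
                            per_sign["positive"]["classes"]
                            | per_sign["negative"]["classes"]
                        )
                    ),
                )
            )
        else:
            slot = per_sign[qualified[0]]
            rows.append(
                ConsensusPairRow(
                    gene_a=a,
                    gene_b=b,
                    direction=qualified[0],
                    supporting_datasets=tuple(sorted(slot["datasets"])),
                    supporting_cell_types=tuple(sorted(slot["types"])),
                    supporting_cell_classes=tuple(sorted(slot["classes"])),
                )
            )
    return ConsensusPairTable(rows, alpha=alpha, min_support=min_support)
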