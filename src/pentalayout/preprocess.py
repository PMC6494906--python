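"""Representative-probe selection, age correction, proportional-contribution
normalization, fold enrichment, and expression-profile classification."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleRecord, to_linear
from .ontology import OntologyMap
from .panel import GenePanel

__all__ = [
    "CompositionMatrix",
    "EnrichmentTable",
    "ProbeScore",
    "select_probe_efa",
    "select_probes",
    "probe_consistency",
    "correct_age",
    "proportional_contribution",
    "global_contribution",
    "fold_enrichment",
    "classify_profiles",
]

log = logging.getLogger(__name__)


class CompositionMatrix:
    """Gene x sample percentages; every column sums to 100.

    Columns whose panel total was zero are excluded at construction (their
    composition is undefined); excluded sample ids are kept on
    ``excluded_samples``.
    """

    def __init__(
        self,
        panel: GenePanel,
        samples: Sequence[SampleRecord],
        values: np.ndarray,
        excluded_samples: Sequence[str] = (),
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(panel), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match panel "
                f"({len(panel)}) x samples ({len(samples)})"
            )
        if np.any(values < -1e-12) or np.any(values > 100 + 1e-9):
            raise ValueError("composition entries must lie in [0, 100]")
        col_sums = values.sum(axis=0)
        if len(samples) and np.max(np.abs(col_sums - 100.0)) > 1e-9:
            j = int(np.argmax(np.abs(col_sums - 100.0)))
            raise ValueError(
                f"column {samples[j].sample_id!r} sums to {col_sums[j]!r}, not 100"
            )
        self.panel = panel
        self.samples = list(samples)
        self.values = values
        self.excluded_samples = list(excluded_samples)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def gene(self, symbol: str) -> np.ndarray:
        return self.values[self.panel.symbols.index(symbol)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.panel.symbols), columns=self.sample_ids
        )


@dataclass(frozen=True)
class EnrichmentRow:
    gene: str
    substructure: str
    mean_log2: float
    fold: float


class EnrichmentTable:
    """Per (gene, substructure): region-average log2 level and linear-scale
    fold enrichment relative to the brain-wide average."""

    def __init__(self, rows: Sequence[EnrichmentRow]):
        for r in rows:
            if r.fold <= 0:
                raise ValueError(
                    f"fold must be > 0; got {r.fold} for ({r.gene}, {r.substructure})"
                )
        self.rows = list(rows)
        self._lookup = {(r.gene, r.substructure): r for r in self.rows}

    def fold(self, gene: str, substructure: str) -> float:
        return self._lookup[(gene, substructure)].fold

    def max_fold(self, gene: str) -> Tuple[str, float]:
        """(argmax substructure, fold) for one gene."""
        best = max(
            (r for r in self.rows if r.gene == gene), key=lambda r: r.fold
        )
        return best.substructure, best.fold

    def genes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.gene)
        return list(seen)

    def to_frame(self, ontology: Optional[OntologyMap] = None) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "gene": r.gene,
                "substructure": r.substructure,
                "mean_log2": r.mean_log2,
                "fold": r.fold,
            }
            if ontology is not None and r.substructure in ontology:
                entry = ontology[r.substructure]
                rec["structure"] = entry.structure
                rec["major_region"] = entry.major_region
            recs.append(rec)
        return pd.DataFrame(recs)

    def summary_frame(self, ontology: Optional[OntologyMap] = None) -> pd.DataFrame:
        """One row per gene at its most-enriched substructure."""
        recs = []
        for g in self.genes():
            sub, fold = self.max_fold(g)
            row = self._lookup[(g, sub)]
            rec = {
                "gene": g,
                "substructure": sub,
                "mean_log2": row.mean_log2,
                "fold": fold,
            }
            if ontology is not None and sub in ontology:
                entry = ontology[sub]
                rec["structure"] = entry.structure
                rec["major_region"] = entry.major_region
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class ProbeScore:
    probe_id: str
    gene: str
    loading: float
    consistency: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.consistency <= 1.0 + 1e-9:
            raise ValueError(f"consistency out of [-1, 1]: {self.consistency}")


# ---------------------------------------------------------------------------
# probe selection


def _first_pc_loadings(values: np.ndarray) -> np.ndarray:
    """Loadings of each row on the first PC of the row correlation
    structure (unrotated); zero-variance rows get loading 0."""
    sd = values.std(axis=1)
    ok = sd > 0
    loadings = np.zeros(values.shape[0])
    if ok.sum() == 0:
        return loadings
    z = (values[ok] - values[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    corr = (z @ z.T) / values.shape[1]
    eigvals, eigvecs = np.linalg.eigh(corr)
    vec = eigvecs[:, -1]
    loadings[ok] = np.sqrt(max(eigvals[-1], 0.0)) * vec
    return loadings


def select_probe_efa(probe_matrix: ExpressionMatrix) -> str:
    """Pick the representative probe for one gene.

    One probe: itself. Two probes: the one with the higher mean expression.
    Three or more: the probe with the largest absolute loading on the first
    principal component of the probe correlation structure; ties broken by
    higher mean expression, then lexicographic probe id.
    """
    n = len(probe_matrix.row_ids)
    if n == 0:
        raise LookupError("no probes supplied")
    if n == 1:
        return probe_matrix.row_ids[0]
    means = probe_matrix.values.mean(axis=1)
    if n == 2:
        order = sorted(
            range(2), key=lambda i: (-means[i], probe_matrix.row_ids[i])
        )
        return probe_matrix.row_ids[order[0]]
    loadings = np.abs(_first_pc_loadings(probe_matrix.values))
    order = sorted(
        range(n), key=lambda i: (-loadings[i], -means[i], probe_matrix.row_ids[i])
    )
    return probe_matrix.row_ids[order[0]]


def select_probes(
    probe_matrix: ExpressionMatrix, probe_to_gene: Dict[str, str]
) -> Dict[str, str]:
    """Representative probe per gene over a multi-gene probe matrix."""
    by_gene: Dict[str, List[str]] = {}
    for pid in probe_matrix.row_ids:
        try:
            by_gene.setdefault(probe_to_gene[pid], []).append(pid)
        except KeyError:
            raise LookupError(f"probe {pid!r} has no gene assignment") from None
    return {
        gene: select_probe_efa(probe_matrix.select_rows(pids))
        for gene, pids in by_gene.items()
    }


def probe_consistency(
    subject_matrices: Sequence[ExpressionMatrix],
    probe_to_gene: Dict[str, str],
) -> List[ProbeScore]:
    """Cross-subject consistency score per probe.

    For each probe, the Pearson correlation of its substructure profile is
    computed between every pair of subjects and averaged. Input matrices
    must be substructure-aggregated with identical column order. Scores are
    returned sorted descending (within descending, by probe id for
    stability). EFA loadings are attached alongside, computed per gene on
    the subject-concatenated profiles.
    """
    if len(subject_matrices) < 2:
        raise ValueError("probe consistency needs at least 2 subjects")
    cols = subject_matrices[0].sample_ids
    for m in subject_matrices[1:]:
        if m.sample_ids != cols:
            raise ValueError("subject matrices must share the substructure columns")
    probe_ids = subject_matrices[0].row_ids
    stacked = np.concatenate([m.values for m in subject_matrices], axis=1)

    loadings: Dict[str, float] = {}
    by_gene: Dict[str, List[str]] = {}
    for pid in probe_ids:
        by_gene.setdefault(probe_to_gene.get(pid, pid), []).append(pid)
    concat = ExpressionMatrix(
        probe_ids,
        [s for m in subject_matrices for s in m.samples],
        stacked,
        subject_matrices[0].scale,
        subject_matrices[0].unit,
    )
    for gene, pids in by_gene.items():
        sub = concat.select_rows(pids)
        if len(pids) >= 2:
            vals = np.abs(_first_pc_loadings(sub.values))
        else:
            vals = np.array([1.0])
        for pid, v in zip(pids, vals):
            loadings[pid] = float(v)

    scores = []
    for i, pid in enumerate(probe_ids):
        rs = []
        for a, b in combinations(range(len(subject_matrices)), 2):
            x = subject_matrices[a].values[i]
            y = subject_matrices[b].values[i]
            if x.std() == 0 or y.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(x, y)[0, 1]))
        scores.append(
            ProbeScore(
                probe_id=pid,
                gene=probe_to_gene.get(pid, pid),
                loading=loadings[pid],
                consistency=float(np.mean(rs)),
            )
        )
    return sorted(scores, key=lambda s: (-s.consistency, s.probe_id))


# ---------------------------------------------------------------------------
# age correction


def correct_age(m: ExpressionMatrix, mode: str = "continuous") -> ExpressionMatrix:
    """Regress out age per gene and add back the gene's grand mean.

    ``continuous`` fits a least-squares line on numeric ages; ``ordinal``
    removes per-category means (categories taken from the sample's numeric
    age or its recorded age category). Constant age leaves the matrix
    untouched with a logged warning.
    """
    if mode not in ("continuous", "ordinal"):
        raise ValueError(f"invalid mode {mode!r}")
    if mode == "continuous":
        ages = []
        for s in m.samples:
            if s.age is None:
                raise ValueError(f"sample {s.sample_id!r} lacks a numeric age")
            ages.append(s.age)
        ages = np.asarray(ages, dtype=float)
        if np.ptp(ages) == 0:
            log.warning("age is constant across samples; correction skipped")
            return ExpressionMatrix(m.row_ids, m.samples, m.values.copy(), m.scale, m.unit)
        centered = ages - ages.mean()
        slopes = (m.values @ centered) / (centered @ centered)
        # residual plus grand mean == raw values minus the fitted slope term
        corrected = m.values - slopes[:, None] * centered[None, :]
    else:
        cats = [
            s.extra.get("age_category") or (str(s.age) if s.age is not None else "")
            for s in m.samples
        ]
        if any(c == "" for c in cats):
            raise ValueError("every sample needs an age category for ordinal mode")
        if len(set(cats)) == 1:
            log.warning("single age category; correction skipped")
            return ExpressionMatrix(m.row_ids, m.samples, m.values.copy(), m.scale, m.unit)
        corrected = m.values.copy()
        grand = m.values.mean(axis=1, keepdims=True)
        for cat in set(cats):
            idx = [j for j, c in enumerate(cats) if c == cat]
            corrected[:, idx] -= m.values[:, idx].mean(axis=1, keepdims=True) - grand
    return ExpressionMatrix(m.row_ids, m.samples, corrected, m.scale, m.unit)


# ---------------------------------------------------------------------------
# compositions


def proportional_contribution(
    m: ExpressionMatrix, panel: GenePanel
) -> CompositionMatrix:
    """Percentage of the linear-scale panel total carried by each gene, per
    sample. Columns with a zero panel total are excluded and logged."""
    missing = [g for g in panel.symbols if g not in m.row_ids]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    linear = to_linear(m.select_rows(list(panel.symbols)))
    sums = linear.values.sum(axis=0)
    ok = sums > 0
    if not ok.all():
        bad = [s.sample_id for s, keep in zip(linear.samples, ok) if not keep]
        log.warning("excluding %d zero-total columns: %s", len(bad), bad[:5])
    vals = linear.values[:, ok] / sums[ok] * 100.0
    # exact renormalization so the sum-to-100 invariant holds bit-for-bit
    vals *= 100.0 / vals.sum(axis=0, keepdims=True)
    return CompositionMatrix(
        panel,
        [s for s, keep in zip(linear.samples, ok) if keep],
        vals,
        excluded_samples=[s.sample_id for s, keep in zip(linear.samples, ok) if not keep],
    )


def global_contribution(m: ExpressionMatrix, panel: GenePanel) -> Dict[str, float]:
    """Each gene's percentage of the brain-wide linear-scale panel total,
    summing over all columns (substructures x subjects)."""
    missing = [g for g in panel.symbols if g not in m.row_ids]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    linear = to_linear(m.select_rows(list(panel.symbols)))
    totals = linear.values.sum(axis=1)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("panel-wide total is zero; global contribution undefined")
    return {g: float(t / grand * 100.0) for g, t in zip(panel.symbols, totals)}


# ---------------------------------------------------------------------------
# enrichment and profile classes


def fold_enrichment(
    m: ExpressionMatrix, panel: GenePanel, ontology: OntologyMap
) -> EnrichmentTable:
    """Linear-scale regional mean over brain-wide mean, per gene and
    substructure, with region-average log2 levels attached.

    ``m`` must be substructure-aggregated (one column per substructure,
    already averaged across subjects). The brain-wide average is the
    unweighted mean of substructure means.
    """
    for s in m.samples:
        if s.substructure not in ontology:
            raise KeyError(f"substructure {s.substructure!r} not in ontology")
    genes = [g for g in panel.symbols if g in m.row_ids]
    sub = m.select_rows(genes)
    linear = to_linear(sub)
    log2_vals = sub.values if sub.scale == "log2" else np.log2(
        np.maximum(linear.values, 1e-300)
    )
    rows = []
    for i, g in enumerate(genes):
        global_mean = linear.values[i].mean()
        if global_mean <= 0:
            warnings.warn(f"gene {g!r} has zero brain-wide mean; enrichment undefined")
            continue
        for j, s in enumerate(m.samples):
            rows.append(
                EnrichmentRow(
                    gene=g,
                    substructure=s.substructure,
                    mean_log2=float(log2_vals[i, j]),
                    fold=float(linear.values[i, j] / global_mean),
                )
            )
    return EnrichmentTable(rows)


def classify_profiles(
    m: ExpressionMatrix,
    enrichment: EnrichmentTable,
    noise_log2: float = 4.0,
    enrich_fold: float = 5.0,
) -> Dict[str, str]:
    """Assign each gene one of three expression profiles.

    noise: brain-wide mean log2 below ``noise_log2`` and no regional fold
    reaching ``enrich_fold``; region_specific: low brain-wide mean (below
    ``1.5 * noise_log2``) but at least one strong regional fold; otherwise
    global_high.
    """
    if m.scale != "log2":
        raise ValueError("classify_profiles expects a log2-scale matrix")
    out = {}
    for i, g in enumerate(m.row_ids):
        mean_log2 = float(m.values[i].mean())
        try:
            _, max_fold = enrichment.max_fold(g)
        except ValueError:
            max_fold = 1.0
        if mean_log2 < noise_log2 and max_fold < enrich_fold:
            out[g] = "noise"
        elif mean_log2 < 1.5 * noise_log2 and max_fold >= enrich_fold:
            out[g] = "region_specific"
        else:
            out[g] = "global_high"
    return out
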