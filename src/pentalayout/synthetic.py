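"""Seeded generators for regional expression, probe-level redundancy, and
single-nucleus compositions with known ground truth.

All generators are pure functions of ``(truth, seed)``: two calls with the
same arguments produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .expression_io import ExpressionMatrix, SampleRecord
from .ontology import OntologyMap, default_ontology
from .panel import GenePanel, default_panel

__all__ = [
    "RegionalTruth",
    "NucleiTruth",
    "simulate_regional",
    "simulate_probes",
    "simulate_nuclei",
    "default_regional_truth",
    "default_nuclei_truth",
]


@dataclass(frozen=True)
class RegionalTruth:
    """Ground truth for the multi-subject regional generator.

    Log2 expression of gene ``g`` in substructure ``r`` for subject ``k`` is

    ``baseline[g] + log2(fold) [if (g, r) enriched]
      + regional term (shared across subjects, SD = regional_sd)
      + sum over co-expression pairs containing g of sign * strength * L[p, r]
      + Normal(0, subject_sd)``

    where each latent factor ``L[p, r]`` is a standard normal draw per pair
    and substructure, shared across subjects so the planted correlation is
    visible both within and across individuals.
    """

    panel: GenePanel
    ontology: OntologyMap
    baseline: Dict[str, float]
    enrichments: Tuple[Tuple[str, str, float], ...] = ()
    coexpression_pairs: Tuple[Tuple[str, str, int, float], ...] = ()
    subject_sd: float = 0.0
    n_subjects: int = 6
    regional_sd: float = 0.0

    def __post_init__(self) -> None:
        for gene, sub, fold in self.enrichments:
            if fold <= 0:
                raise ValueError(f"enrichment fold must be > 0, got {fold} for {gene}")
            if gene not in self.panel:
                raise ValueError(f"enrichment gene {gene!r} not in panel")
            if sub not in self.ontology:
                raise ValueError(f"enrichment substructure {sub!r} not in ontology")
        for a, b, sign, strength in self.coexpression_pairs:
            if sign not in (-1, 1):
                raise ValueError(f"pair sign must be +/-1, got {sign}")
            if not 0 < strength <= 1:
                raise ValueError(f"pair strength must be in (0, 1], got {strength}")
            if a not in self.panel or b not in self.panel:
                raise ValueError(f"pair genes ({a!r}, {b!r}) not in panel")
        if self.subject_sd < 0 or self.regional_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        missing = [g for g in self.panel.symbols if g not in self.baseline]
        if missing:
            raise ValueError(f"baseline missing genes: {missing}")


@dataclass(frozen=True)
class NucleiTruth:
    """Ground truth for the single-nucleus composition generator.

    ``cell_types`` holds ``(name, cell class, mean composition)`` triples
    where each mean composition covers the panel genes and sums to 100.
    ``tradeoff_pairs`` plant within-type positive or negative co-variation
    between two genes (sign, strength in (0, 1]).
    """

    panel: GenePanel
    n_nuclei: int
    cell_types: Tuple[Tuple[str, str, Tuple[float, ...]], ...]
    composition_concentration: float = 200.0
    dropout_rate: float = 0.0
    tradeoff_pairs: Tuple[Tuple[str, str, int, float], ...] = ()
    library_size: int = 1000

    def __post_init__(self) -> None:
        n = len(self.panel)
        for name, klass, mean in self.cell_types:
            if klass not in ("excitatory", "inhibitory", "non_neuronal"):
                raise ValueError(f"invalid cell class {klass!r} for {name!r}")
            if len(mean) != n:
                raise ValueError(
                    f"cell type {name!r} mean has {len(mean)} entries, panel has {n}"
                )
            if abs(sum(mean) - 100.0) > 1e-9:
                raise ValueError(f"cell type {name!r} mean does not sum to 100")
            if any(v < 0 for v in mean):
                raise ValueError(f"cell type {name!r} mean has negative entries")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.composition_concentration <= 0:
            raise ValueError("composition_concentration must be positive")
        for a, b, sign, strength in self.tradeoff_pairs:
            if sign not in (-1, 1) or not 0 < strength <= 1:
                raise ValueError(f"bad tradeoff pair ({a}, {b}, {sign}, {strength})")


# ---------------------------------------------------------------------------
# regional


def simulate_regional(
    truth: RegionalTruth, seed: int
) -> Tuple[List[ExpressionMatrix], OntologyMap]:
    """Generate one substructure-level log2 matrix per subject."""
    rng = np.random.default_rng(seed)
    genes = list(truth.panel.symbols)
    subs = truth.ontology.substructures
    g_idx = {g: i for i, g in enumerate(genes)}
    r_idx = {r: j for j, r in enumerate(subs)}
    n_g, n_r = len(genes), len(subs)

    shared = np.array([[truth.baseline[g]] * n_r for g in genes], dtype=float)
    for gene, sub, fold in truth.enrichments:
        shared[g_idx[gene], r_idx[sub]] += math.log2(fold)
    if truth.regional_sd > 0:
        shared += rng.normal(0.0, truth.regional_sd, size=(n_g, n_r))
    for a, b, sign, strength in truth.coexpression_pairs:
        latent = rng.standard_normal(n_r)
        shared[g_idx[a]] += strength * latent
        shared[g_idx[b]] += sign * strength * latent

    matrices = []
    for k in range(truth.n_subjects):
        vals = shared.copy()
        if truth.subject_sd > 0:
            vals += rng.normal(0.0, truth.subject_sd, size=(n_g, n_r))
        subject = f"S{k + 1:02d}"
        records = [
            SampleRecord(sample_id=code, subject_id=subject, substructure=code)
            for code in subs
        ]
        matrices.append(
            ExpressionMatrix(genes, records, vals, scale="log2", unit="intensity")
        )
    return matrices, truth.ontology


def default_regional_truth(
    n_subjects: int = 6,
    subject_sd: float = 0.3,
    regional_sd: float = 1.0,
    panel: Optional[GenePanel] = None,
    ontology: Optional[OntologyMap] = None,
) -> RegionalTruth:
    """Desk-scale default mimicking the study design: 6 subjects, the
    packaged 111-substructure ontology, the 19-gene panel, a handful of
    planted enrichments and signed co-expression pairs."""
    panel = panel or default_panel()
    ontology = ontology or default_ontology()
    baseline = {
        g: (3.0 if panel.family[g] in ("rho", "pi") else 8.0) for g in panel.symbols
    }
    enrichments = (
        ("GABRA6", "PV-V", 200.0),
        ("GABRQ", "DG", 30.0),
        ("GABRE", "PrOR", 13.0),
        ("GABRG1", "CeA", 10.0),
    )
    pairs = (
        ("GABRA1", "GABRB2", +1, 0.9),
        ("GABRA2", "GABRB3", +1, 0.9),
        ("GABRB1", "GABRB2", -1, 0.9),
        ("GABRA3", "GABRD", -1, 0.9),
    )
    return RegionalTruth(
        panel=panel,
        ontology=ontology,
        baseline=baseline,
        enrichments=enrichments,
        coexpression_pairs=pairs,
        subject_sd=subject_sd,
        n_subjects=n_subjects,
        regional_sd=regional_sd,
    )


# ---------------------------------------------------------------------------
# probes


def simulate_probes(
    regional: Sequence[ExpressionMatrix],
    probes_per_gene: int,
    noise_sd: float,
    seed: int,
) -> Tuple[List[ExpressionMatrix], Dict[str, str]]:
    """Expand gene-level subject matrices into redundant probe-level ones.

    Probe 1 of each gene tracks the gene with noise SD ``noise_sd / 10``
    (the faithful probe). Remaining probes cycle through attenuated,
    more-attenuated, region-shuffled, and constant variants. Returns the
    per-subject probe matrices and the ``gene -> faithful probe id`` map.
    """
    if probes_per_gene < 2:
        raise ValueError("probes_per_gene must be >= 2")
    if not regional:
        raise ValueError("need at least one subject matrix")
    rng = np.random.default_rng(seed)
    genes = regional[0].row_ids
    n_r = regional[0].shape[1]

    # (scale, extra noise multiplier, kind); shuffling permutes regions
    # independently per subject so cross-subject consistency collapses.
    variant_cycle = [
        (0.5, 1.0, "attenuated"),
        (0.3, 2.0, "attenuated"),
        (0.5, 1.0, "shuffled"),
        (0.0, 0.0, "constant"),
    ]

    probe_ids: List[str] = []
    plans: List[Tuple[str, int, Tuple[float, float, str]]] = []
    truth_map: Dict[str, str] = {}
    for g in genes:
        faithful_id = f"{g}_p1"
        truth_map[g] = faithful_id
        probe_ids.append(faithful_id)
        plans.append((g, 0, (1.0, 0.1, "faithful")))
        for k in range(1, probes_per_gene):
            scale, mult, kind = variant_cycle[(k - 1) % len(variant_cycle)]
            probe_ids.append(f"{g}_p{k + 1}")
            plans.append((g, k, (scale, mult, kind)))

    # constant offsets and shuffle permutations are per probe; noise is per
    # probe, subject and region
    out = []
    perms = {
        i: [rng.permutation(n_r) for _ in regional]
        for i, (_, k, (_, _, kind)) in enumerate(plans)
        if kind == "shuffled"
    }
    for s_idx, m in enumerate(regional):
        rows = np.empty((len(plans), n_r))
        for i, (g, _, (scale, mult, kind)) in enumerate(plans):
            base = m.row(g)
            if kind == "faithful":
                rows[i] = base + (
                    rng.normal(0.0, noise_sd / 10.0, n_r) if noise_sd > 0 else 0.0
                )
            elif kind == "attenuated":
                noise = rng.normal(0.0, noise_sd * mult, n_r) if noise_sd > 0 else 0.0
                rows[i] = scale * base + noise
            elif kind == "shuffled":
                noise = rng.normal(0.0, noise_sd * mult, n_r) if noise_sd > 0 else 0.0
                rows[i] = scale * base[perms[i][s_idx]] + noise
            else:  # constant
                rows[i] = float(base.mean())
        out.append(
            ExpressionMatrix(probe_ids, m.samples, rows, scale=m.scale, unit=m.unit)
        )
    return out, truth_map


# ---------------------------------------------------------------------------
# nuclei


def simulate_nuclei(
    truth: NucleiTruth, seed: int
) -> Tuple[ExpressionMatrix, List[SampleRecord]]:
    """Draw nucleus compositions around their cell-type means and convert
    to linear counts with per-gene dropout.

    Returns the counts matrix (genes x nuclei) and the per-nucleus labels
    (which the matrix's samples also carry).
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.panel.symbols)
    g_idx = {g: i for i, g in enumerate(genes)}
    comps = []
    records = []
    n = 0
    for name, klass, mean in truth.cell_types:
        mean = np.asarray(mean, dtype=float)
        for _ in range(truth.n_nuclei):
            if math.isinf(truth.composition_concentration):
                comp = mean.copy()
            else:
                alpha = np.maximum(
                    mean / 100.0 * truth.composition_concentration, 1e-12
                )
                comp = rng.dirichlet(alpha) * 100.0
            for a, b, sign, strength in truth.tradeoff_pairs:
                ia, ib = g_idx[a], g_idx[b]
                mass = comp[ia] + comp[ib]
                if mass <= 0:
                    continue
                if sign < 0:
                    # bimodal split of the shared mass between the two genes
                    lo = max(1e-3, 2.0 * (1.0 - strength))
                    t = rng.beta(lo, lo)
                    comp[ia], comp[ib] = t * mass, (1.0 - t) * mass
                else:
                    # common multiplicative factor, renormalized panel-wide
                    factor = math.exp(rng.normal(0.0, 1.5 * strength))
                    comp[ia] *= factor
                    comp[ib] *= factor
                    comp *= 100.0 / comp.sum()
            if truth.dropout_rate > 0:
                drop = rng.random(len(genes)) < truth.dropout_rate
                comp = np.where(drop, 0.0, comp)
            comps.append(comp)
            n += 1
            records.append(
                SampleRecord(
                    sample_id=f"N{n:06d}",
                    subject_id="sn01",
                    cell_type=name,
                    cell_class=klass,
                )
            )
    counts = np.column_stack(comps) / 100.0 * truth.library_size
    matrix = ExpressionMatrix(genes, records, counts, scale="linear", unit="counts")
    return matrix, records


def default_nuclei_truth(
    n_nuclei: int = 200,
    n_excitatory: int = 24,
    n_inhibitory: int = 45,
    n_non_neuronal: int = 7,
    dropout_rate: float = 0.1,
    concentration: float = 200.0,
    tradeoff_pairs: Tuple[Tuple[str, str, int, float], ...] = (),
    panel: Optional[GenePanel] = None,
    mean_seed: int = 12345,
) -> NucleiTruth:
    """Cell-type means concentrated near the 40/40/20 family split.

    Per type, each family's total mass is jittered around its target and
    spread across that family's genes with a random (but seeded) profile,
    giving distinct, reproducible cell-type signatures.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(mean_seed)
    targets = {"SigmaAlpha": 40.0, "SigmaBeta": 40.0, "SigmaChi": 19.0, "excluded": 1.0}
    types = []
    specs = (
        [("Exc", "excitatory")] * n_excitatory
        + [("Inh", "inhibitory")] * n_inhibitory
        + [("NonN", "non_neuronal")] * n_non_neuronal
    )
    counters: Dict[str, int] = {}
    for prefix, klass in specs:
        counters[prefix] = counters.get(prefix, 0) + 1
        name = f"{prefix}{counters[prefix]:02d}"
        mass = {
            tag: max(target + rng.normal(0.0, 0.5), 0.1)
            for tag, target in targets.items()
        }
        total = sum(mass.values())
        mean = np.empty(len(panel))
        for tag in targets:
            members = panel.members_of(tag)
            weights = rng.dirichlet(np.full(len(members), 2.0))
            for sym, w in zip(members, weights):
                mean[panel.symbols.index(sym)] = mass[tag] / total * 100.0 * w
        mean *= 100.0 / mean.sum()
        types.append((name, klass, tuple(mean)))
    return NucleiTruth(
        panel=panel,
        n_nuclei=n_nuclei,
        cell_types=tuple(types),
        composition_concentration=concentration,
        dropout_rate=dropout_rate,
        tradeoff_pairs=tradeoff_pairs,
    )
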