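"""Synthetic data with known ground truth for every analysis stage.

The expression generator emulates a targeted-microarray cytotoxicity
study: untreated control replicates plus treated replicates at each of a
small set of peptide concentrations (default 1.25, 2.5 and 5 uM, in
triplicate), probes tiling a gene panel organised into weighted pathways.
Perturbations are planted at the pathway level and propagated to genes
respecting the activator/repressor weights — activators move with the
planted log2 fold-change, repressors opposite, half-weight genes with half
the log effect, ARR = 0 genes not at all — so the expected PAS of a
planted pathway is analytically

    PAS = lfc * log10(2) * sum(ARR^2) / N.

All generators consume a single integer seed and are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import DoseResponseDataset, four_param_logistic
from .cytometry import QuadrantFractions
from .pathways import ARR_VALUES, PathwayDB, ProbeMatrix

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "gen_expression_study",
    "gen_dose_response",
    "gen_cytometry",
    "gen_plate",
    "DEFAULT_CHANNEL_PARAMS",
]

#: ARR weights cycled over the genes of each generated pathway; every
#: pathway therefore contains activators, repressors, half-weight genes
#: and an unknown-role gene, like a curated signaling pathway would.
_ARR_CYCLE = (1.0, 1.0, -1.0, 0.5, -0.5, 0.0)


@dataclass
class StudyDesign:
    """Design of a synthetic expression study.

    Defaults emulate the full-scale study design: a 2016-gene panel
    covering 334 signaling pathways, untreated controls in triplicate and
    treatment in triplicate at 1.25, 2.5 and 5 uM.  Tests use a
    proportionally reduced panel (200 genes / 20 pathways).
    """

    n_genes: int = 2016
    probes_per_gene: int = 1
    n_pathways: int = 334
    genes_per_pathway: int = 6
    concentrations: tuple[float, ...] = (1.25, 2.5, 5.0)
    replicates: int = 3
    control_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    #: pathway id -> log2 fold-change, either a scalar (applied at every
    #: concentration) or a {concentration: lfc} map
    planted_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.probes_per_gene, self.n_pathways,
               self.genes_per_pathway, self.replicates, self.control_replicates) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if list(self.concentrations) != sorted(set(self.concentrations)):
            raise ValueError("concentrations must be strictly increasing")

    def effect_at(self, pathway: str, concentration: float) -> float:
        eff = self.planted_effects.get(pathway, 0.0)
        if isinstance(eff, dict):
            return float(eff.get(concentration, 0.0))
        return float(eff)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    #: pathway -> concentration -> planted log2 fold-change
    pathway_effects: dict
    #: pathway -> concentration -> analytically expected PAS
    expected_pas: dict
    #: gene -> concentration -> true log2 shift applied
    gene_log2fc: dict
    design: StudyDesign

    def direction(self, pathway: str, concentration: float) -> str:
        lfc = self.pathway_effects.get(pathway, {}).get(concentration, 0.0)
        if lfc > 0:
            return "activated"
        if lfc < 0:
            return "repressed"
        return "neutral"


def _build_pathway_db(design: StudyDesign) -> PathwayDB:
    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    pathways: dict[str, dict[str, float]] = {}
    names = {}
    for p in range(design.n_pathways):
        pid = f"pw{p:04d}"
        start = (p * design.genes_per_pathway) % design.n_genes
        members = [genes[(start + k) % design.n_genes] for k in range(design.genes_per_pathway)]
        pathways[pid] = {g: _ARR_CYCLE[k % len(_ARR_CYCLE)] for k, g in enumerate(members)}
        names[pid] = f"synthetic pathway {p}"
    return PathwayDB(pathways, names)


def gen_expression_study(design: StudyDesign) -> tuple[ProbeMatrix, PathwayDB, GroundTruth]:
    """Simulate a probe matrix with planted pathway perturbations.

    Baseline gene intensities are log-normal; treated samples shift the
    genes of perturbed pathways by ``ARR * lfc`` on the log2 scale; probes
    scatter around their gene's value with log2 noise ``noise_sd``; the
    same noise is applied per (probe, sample).
    """
    db = _build_pathway_db(design)
    for pid in design.planted_effects:
        if pid not in db.pathways:
            raise ValueError(f"planted pathway {pid!r} not in the generated database")

    rng = np.random.default_rng(design.seed)
    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    baseline = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd,
                          size=design.n_genes)

    # per-gene log2 shift for each concentration, from the planted pathways
    shift = {c: np.zeros(design.n_genes) for c in design.concentrations}
    gene_pos = {g: i for i, g in enumerate(genes)}
    gene_log2fc: dict[str, dict[float, float]] = {}
    for pid, members in db.pathways.items():
        for c in design.concentrations:
            lfc = design.effect_at(pid, c)
            if lfc == 0.0:
                continue
            for g, arr in members.items():
                delta = arr * lfc
                shift[c][gene_pos[g]] += delta
                gene_log2fc.setdefault(g, {})[c] = gene_log2fc.get(g, {}).get(c, 0.0) + delta

    sample_ids, groups, concs, reps = [], [], [], []
    columns = {}
    probe_ids = [f"{g}_p{j}" for g in genes for j in range(design.probes_per_gene)]
    probe_gene = [g for g in genes for _ in range(design.probes_per_gene)]

    def _sample(gene_log2: np.ndarray) -> np.ndarray:
        per_probe = np.repeat(gene_log2, design.probes_per_gene)
        noise = rng.normal(0.0, design.noise_sd, size=per_probe.size) if design.noise_sd > 0 \
            else np.zeros(per_probe.size)
        return 2.0 ** (per_probe + noise)

    for r in range(design.control_replicates):
        sid = f"control_r{r + 1}"
        columns[sid] = _sample(baseline)
        sample_ids.append(sid); groups.append("control"); concs.append(0.0); reps.append(r + 1)
    for c in design.concentrations:
        for r in range(design.replicates):
            sid = f"treated_{c:g}uM_r{r + 1}"
            columns[sid] = _sample(baseline + shift[c])
            sample_ids.append(sid); groups.append("treated"); concs.append(c); reps.append(r + 1)

    signals = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    samples = pd.DataFrame(
        {"group": groups, "concentration_uM": concs, "replicate": reps},
        index=pd.Index(sample_ids, name="sample"),
    )
    probes = ProbeMatrix(
        signals=signals,
        probe_to_gene=pd.Series(probe_gene, index=signals.index, name="gene"),
        samples=samples,
    )

    pathway_effects, expected_pas = {}, {}
    for pid, members in db.pathways.items():
        arr2 = sum(a * a for a in members.values())
        n = len(members)
        for c in design.concentrations:
            lfc = design.effect_at(pid, c)
            if lfc == 0.0:
                continue
            pathway_effects.setdefault(pid, {})[c] = lfc
            expected_pas.setdefault(pid, {})[c] = lfc * math.log10(2.0) * arr2 / n
    truth = GroundTruth(pathway_effects=pathway_effects, expected_pas=expected_pas,
                        gene_log2fc=gene_log2fc, design=design)
    return probes, db, truth


def gen_dose_response(ic50: float, hill: float, top: float, bottom: float,
                      doses, noise_sd: float, replicates: int, seed: int,
                      cell_line: str = "", peptide: str = "",
                      rising: bool = False) -> DoseResponseDataset:
    """4PL mean response plus Gaussian noise at each (dose, replicate)."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    conc = np.repeat(doses, replicates)
    signed_hill = -abs(hill) if rising else abs(hill)
    mean = four_param_logistic(conc, top, bottom, math.log10(ic50), signed_hill)
    noise = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
    rep = np.tile(np.arange(1, replicates + 1), len(doses))
    return DoseResponseDataset(conc, mean + noise, replicate=rep,
                               cell_line=cell_line, peptide=peptide)


#: (log10 mean AV, log10 mean PI, log10 sd) per quadrant — well separated
DEFAULT_CHANNEL_PARAMS = {
    "viable": ((1.0, 0.15), (1.0, 0.15)),
    "early_apoptotic": ((3.0, 0.15), (1.0, 0.15)),
    "late_apoptotic_necrotic": ((3.0, 0.15), (3.0, 0.15)),
    "av_neg_pi_pos": ((1.0, 0.15), (3.0, 0.15)),
}


def gen_cytometry(fractions: QuadrantFractions, n_events: int, seed: int,
                  channel_params: dict | None = None,
                  concentration_uM: float = math.nan, time_h: float = math.nan,
                  inhibitor: str = "none") -> pd.DataFrame:
    """Mixture of four bivariate log-normal clouds with the planted weights."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    params = channel_params or DEFAULT_CHANNEL_PARAMS
    for quad, ((_, sd_av), (_, sd_pi)) in params.items():
        if sd_av < 0 or sd_pi < 0:
            raise ValueError(f"negative channel sd for quadrant {quad!r}")
    rng = np.random.default_rng(seed)
    weights = [fractions.viable, fractions.early_apoptotic,
               fractions.late_apoptotic_necrotic, fractions.av_neg_pi_pos]
    quads = list(DEFAULT_CHANNEL_PARAMS)
    component = rng.choice(4, size=n_events, p=weights)
    av = np.empty(n_events)
    pi = np.empty(n_events)
    for k, quad in enumerate(quads):
        idx = component == k
        (m_av, s_av), (m_pi, s_pi) = params[quad]
        av[idx] = 10.0 ** rng.normal(m_av, s_av, size=int(idx.sum()))
        pi[idx] = 10.0 ** rng.normal(m_pi, s_pi, size=int(idx.sum()))
    return pd.DataFrame({
        "event_id": np.arange(1, n_events + 1),
        "av": av, "pi": pi,
        "concentration_uM": concentration_uM, "time_h": time_h,
        "inhibitor": inhibitor,
        "true_quadrant": [quads[k] for k in component],
    })


def gen_plate(assay: str, true_percent_per_dose: dict, control_ods: tuple[float, float],
              noise_sd: float, seed: int, replicates: int = 3) -> pd.DataFrame:
    """Back-compute sample ODs from planted percentages, plus Gaussian OD noise.

    ``assay`` is one of hemolysis / ldh / mtt; ``control_ods`` is the
    (low-control, high-control) OD pair the percent formula divides by.
    Returns a tidy plate table (well, role, concentration_uM, replicate, od).
    """
    roles = {
        "hemolysis": ("zero_lysis_control", "full_lysis_control"),
        "ldh": ("spontaneous", "maximal"),
        "mtt": ("blank", "untreated"),
    }
    if assay not in roles:
        raise ValueError(f"unknown assay {assay!r}")
    low, high = control_ods
    if high <= low:
        raise ValueError("high control OD must exceed the low control OD")
    low_role, high_role = roles[assay]
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def _add(role, conc, rep, od):
        nonlocal well
        well += 1
        rows.append({"well": f"W{well:03d}", "role": role,
                     "concentration_uM": conc, "replicate": rep,
                     "od": max(od, 0.0)})

    for rep in range(1, replicates + 1):
        _add(low_role, math.nan, rep, low + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0))
        _add(high_role, math.nan, rep, high + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0))
    for conc in sorted(true_percent_per_dose):
        pct = true_percent_per_dose[conc]
        target = low + pct / 100.0 * (high - low)
        for rep in range(1, replicates + 1):
            _add("sample", float(conc), rep,
                 target + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0))
    return pd.DataFrame(rows)
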