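"""Pathway activation scoring from probe-level expression data.

The pipeline mirrors the standard bioinformatic treatment of a targeted
expression chip:

1. probe signals are floored and geometrically averaged per gene;
2. samples are quantile normalized (each sample's sorted values are
   replaced by the across-sample mean of sorted values; tied values within
   a sample receive the mean of their target quantiles);
3. each treated sample's genes are expressed as case-to-normal ratios
   (CNR): case intensity over the arithmetic mean of the control group;
4. per pathway p with gene weights ARR (activator/repressor role, one of
   {-1, -0.5, 0, 0.5, 1}), the pathway activation strength is

       PAS_p = sum_n ARR_np * log10(CNR_n) / N

   where both the sum and N run over pathway genes present in the data.

PAS is signed: positive means the pathway is activated relative to
controls, negative that it is repressed.  The score carries no null model;
activation/repression calls are sign-based only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARR_VALUES",
    "ProbeMatrix",
    "PathwayDB",
    "PASProfile",
    "aggregate_probes",
    "quantile_normalize",
    "compute_cnr",
    "compute_pas",
    "classify_pathways",
    "PathwayActivation",
    "PathwayActivationResults",
]

#: permitted activator/repressor role weights
ARR_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus probe->gene map and sample annotations.

    ``signals``: DataFrame probes x samples (non-negative intensities).
    ``probe_to_gene``: Series indexed by probe_id giving the gene symbol;
    every probe maps to exactly one gene, a gene may own several probes.
    ``samples``: DataFrame indexed by sample id with columns ``group``
    ({control, treated}), ``concentration_uM`` and ``replicate``.
    """

    signals: pd.DataFrame
    probe_to_gene: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("probe signals must be non-negative")
        unmapped = self.signals.index.difference(self.probe_to_gene.index)
        if len(unmapped):
            raise ValueError(f"probes without a gene mapping: {list(unmapped[:5])}")
        missing = self.samples.index.difference(self.signals.columns)
        if len(missing):
            raise ValueError(f"annotated samples absent from the matrix: {list(missing)}")

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "control"])

    @property
    def treated_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "treated"])


class PathwayDB:
    """Gene sets with activator/repressor role weights.

    ``pathways`` maps pathway_id -> dict gene -> ARR weight; ``names`` holds
    display names.  Weights outside {-1, -0.5, 0, 0.5, 1} are rejected.
    """

    def __init__(self, pathways: dict[str, dict[str, float]],
                 names: dict[str, str] | None = None) -> None:
        for pid, genes in pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has no genes")
            for gene, arr in genes.items():
                if float(arr) not in ARR_VALUES:
                    raise ValueError(
                        f"pathway {pid!r}, gene {gene!r}: ARR {arr!r} not in {ARR_VALUES}"
                    )
        self.pathways = {pid: {g: float(a) for g, a in genes.items()}
                         for pid, genes in pathways.items()}
        self.names = dict(names or {})

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __eq__(self, other) -> bool:
        return isinstance(other, PathwayDB) and self.pathways == other.pathways \
            and self.names == other.names

    def genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= set(genes)
        return out


def aggregate_probes(probes: ProbeMatrix, floor: float = 1.0) -> pd.DataFrame:
    """Collapse probes to genes by the geometric mean of floored signals.

    Signals below ``floor`` are raised to it before averaging, which keeps
    zeros out of the log domain.  Returns a genes x samples DataFrame.
    """
    if floor <= 0:
        raise ValueError("floor must be strictly positive")
    floored = np.log(self_floor(probes.signals, floor))
    gene_of = probes.probe_to_gene.reindex(probes.signals.index)
    expr = np.exp(floored.groupby(gene_of).mean())
    expr.index.name = "gene"
    return expr


def self_floor(df: pd.DataFrame, floor: float) -> pd.DataFrame:
    return df.clip(lower=floor)


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean of the sorted distributions.

    After normalization each column's sorted values equal the across-sample
    mean of sorted values; ties within a column receive the mean of the
    target quantile values of the tied rank positions (the behaviour of
    limma's normalizeQuantiles with ties).  Idempotent.
    """
    if expr.shape[1] < 2:
        warnings.warn("quantile normalization of a single sample is the identity",
                      stacklevel=2)
        return expr.copy()
    values = expr.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average target values over runs of tied input values
        sorted_col = col[order]
        i = 0
        while i < len(col):
            k = i
            while k + 1 < len(col) and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                assigned[order[i:k + 1]] = target[i:k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def compute_cnr(expr: pd.DataFrame, case: str, controls: list[str]) -> pd.Series:
    """Case-to-normal ratio per gene: case over the control-group mean."""
    controls = list(controls)
    if not controls:
        raise ValueError("control group is empty")
    if case in controls:
        raise ValueError(f"case sample {case!r} cannot be part of the control group")
    control_mean = expr[controls].mean(axis=1)
    if (control_mean <= 0).any():
        bad = control_mean.index[control_mean <= 0][:5]
        raise ValueError(f"non-positive control mean for genes {list(bad)}")
    cnr = expr[case] / control_mean
    cnr.name = case
    return cnr


def compute_pas(cnr: pd.Series, db: PathwayDB) -> pd.DataFrame:
    """Pathway activation strength per pathway for one CNR vector.

    PAS_p = sum(ARR * log10(CNR)) / N over the pathway genes present in the
    CNR vector; genes absent from the data are excluded from both the sum
    and N.  Pathways with no measured gene are reported as missing (NaN)
    rather than zero.  Returns a DataFrame with columns ``pas``,
    ``n_genes_used`` and ``call``.
    """
    logc = np.log10(cnr)
    rows = []
    for pid, genes in db.pathways.items():
        present = [g for g in genes if g in logc.index]
        if not present:
            rows.append((pid, math.nan, 0, "missing"))
            continue
        score = sum(genes[g] * logc[g] for g in present) / len(present)
        rows.append((pid, score, len(present), _call(score)))
    out = pd.DataFrame(rows, columns=["pathway", "pas", "n_genes_used", "call"])
    return out.set_index("pathway")


def _call(pas: float) -> str:
    if pas > 0:
        return "activated"
    if pas < 0:
        return "repressed"
    return "neutral"


def classify_pathways(profile: pd.DataFrame, planted_truth: dict[str, str] | None = None):
    """Sign-based activation/repression calls, optionally scored against truth.

    ``profile`` is a compute_pas output.  With ``planted_truth`` (pathway ->
    'activated'/'repressed'/'neutral'), returns ``(calls, confusion)`` where
    confusion counts agreements and disagreements on the truth's pathways.
    """
    calls = profile["call"].copy()
    if planted_truth is None:
        return calls
    confusion = {"correct": 0, "wrong_sign": 0, "missing": 0}
    for pid, truth in planted_truth.items():
        got = calls.get(pid, "missing")
        if got == "missing":
            confusion["missing"] += 1
        elif got == truth:
            confusion["correct"] += 1
        else:
            confusion["wrong_sign"] += 1
    return calls, confusion


@dataclass
class PathwayActivationResults:
    """Fitted pathway-activation profile for one expression study.

    Attributes
    ----------
    expression : genes x samples DataFrame after probe aggregation and
        quantile normalization.
    cnr : genes x treated-samples DataFrame of case-to-normal ratios.
    pas : long DataFrame (pathway, sample, pas, n_genes_used, call).
    group_pas : pathway x concentration DataFrame of replicate-mean PAS.
    """

    expression: pd.DataFrame
    cnr: pd.DataFrame
    pas: pd.DataFrame
    group_pas: pd.DataFrame
    samples: pd.DataFrame
    db: PathwayDB = field(repr=False, default=None)

    def profile(self, sample: str) -> pd.DataFrame:
        sub = self.pas[self.pas["sample"] == sample]
        return sub.set_index("pathway")[["pas", "n_genes_used", "call"]]

    def summary(self, top: int = 10) -> str:
        """Human-readable digest: strongest group-level activations/repressions."""
        mean_pas = self.group_pas.mean(axis=1).dropna().sort_values()
        lines = [
            "Pathway activation analysis",
            "=" * 41,
            f"samples: {len(self.samples)} "
            f"({(self.samples['group'] == 'control').sum()} control, "
            f"{(self.samples['group'] == 'treated').sum()} treated)",
            f"genes measured: {self.expression.shape[0]}; pathways scored: {len(self.group_pas)}",
            "",
            "most repressed (mean PAS over concentrations):",
        ]
        for pid, v in mean_pas.head(top).items():
            lines.append(f"  {pid:<24s} {v:+.4f}")
        lines.append("most activated:")
        for pid, v in mean_pas.tail(top).sort_values(ascending=False).items():
            lines.append(f"  {pid:<24s} {v:+.4f}")
        return "\n".join(lines)

    def plot(self, pathway: str, ax=None):
        """Per-sample PAS of one pathway against treatment concentration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.pas[self.pas["pathway"] == pathway].copy()
        conc = self.samples.loc[sub["sample"], "concentration_uM"].to_numpy()
        ax.plot(conc, sub["pas"].to_numpy(), "o")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("PAS")
        ax.set_title(pathway)
        return ax


class PathwayActivation:
    """Model: probe matrix + pathway DB -> per-sample PAS profiles.

    Each treated sample is scored individually against the pooled control
    group; a group-level PAS (mean over the replicates of each
    concentration) is reported alongside.

    Parameters
    ----------
    probes : ProbeMatrix
    db : PathwayDB
    floor : intensity floor applied before geometric probe averaging and
        again before ratios (default 1.0 on the raw-intensity scale).
    normalize : whether to quantile normalize after probe aggregation.
    """

    def __init__(self, probes: ProbeMatrix, db: PathwayDB, floor: float = 1.0,
                 normalize: bool = True) -> None:
        self.probes = probes
        self.db = db
        self.floor = floor
        self.normalize = normalize

    def fit(self) -> PathwayActivationResults:
        expr = aggregate_probes(self.probes, floor=self.floor)
        if self.normalize:
            expr = quantile_normalize(expr)
        expr = self_floor(expr, self.floor)

        controls = self.probes.control_samples
        treated = self.probes.treated_samples
        if not controls:
            raise ValueError("no control samples annotated")
        if not treated:
            raise ValueError("no treated samples annotated")

        cnr = pd.DataFrame({s: compute_cnr(expr, s, controls) for s in treated})
        long = []
        for s in treated:
            prof = compute_pas(cnr[s], self.db)
            prof = prof.assign(sample=s).reset_index()
            long.append(prof)
        pas = pd.concat(long, ignore_index=True)[
            ["pathway", "sample", "pas", "n_genes_used", "call"]]

        conc = self.probes.samples["concentration_uM"]
        with_conc = pas.assign(concentration_uM=conc.loc[pas["sample"]].to_numpy())
        group = with_conc.pivot_table(index="pathway", columns="concentration_uM",
                                      values="pas", aggfunc="mean")
        return PathwayActivationResults(
            expression=expr, cnr=cnr, pas=pas, group_pas=group,
            samples=self.probes.samples, db=self.db,
        )
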