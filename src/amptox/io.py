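"""File formats: FASTA peptides, TSV tables, weighted gene-set text, results.

One tabular dialect is used throughout: tab-separated values with ``#``
comment lines, no CSV autodetection.  Gene and probe identifiers are
opaque case-sensitive strings.  Writers sort rows and fix float formatting
(6 significant digits) so reruns produce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .pathways import ARR_VALUES, PathwayDB, ProbeMatrix
from .peptides import CTerm, PeptideSequence, parse_peptide

__all__ = [
    "ParseError",
    "read_fasta",
    "read_pathway_db",
    "write_pathway_db",
    "read_plate_tsv",
    "read_events_tsv",
    "read_probe_matrix",
    "write_tsv",
    "write_results",
    "RunConfig",
]

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; message carries file/line context."""


def read_fasta(path, cterm: CTerm | str = CTerm.FREE_ACID) -> list[PeptideSequence]:
    """Read peptides from a FASTA file; record ids become names."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise ParseError(f"{path}:{lineno}: sequence data before first FASTA header")
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    return [parse_peptide(str(rec.seq), cterm=cterm, name=rec.id)
            for rec in SeqIO.parse(str(path), "fasta")]


def read_pathway_db(path) -> PathwayDB:
    """Parse a weighted gene-set file.

    One pathway per line: ``pathway_id<TAB>description<TAB>gene:ARR ...``
    with ARR from {-1, -0.5, 0, 0.5, 1}.
    """
    path = Path(path)
    pathways: dict[str, dict[str, float]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected pathway_id, description, genes")
            pid, desc, *tokens = parts
            genes: dict[str, float] = {}
            for tok in tokens:
                if not tok:
                    continue
                gene, sep, arr_text = tok.rpartition(":")
                if not sep or not gene:
                    raise ParseError(f"{path}:{lineno}: token {tok!r} is not gene:ARR")
                try:
                    arr = float(arr_text)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: pathway {pid!r}, gene {gene!r}: "
                                     f"ARR {arr_text!r} is not a number") from None
                if arr not in ARR_VALUES:
                    raise ParseError(f"{path}:{lineno}: pathway {pid!r}, gene {gene!r}: "
                                     f"ARR {arr} not in {ARR_VALUES}")
                if gene in genes:
                    raise ParseError(f"{path}:{lineno}: pathway {pid!r}: duplicate gene {gene!r}")
                genes[gene] = arr
            if pid in pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            pathways[pid] = genes
            names[pid] = desc
    return PathwayDB(pathways, names)


def write_pathway_db(db: PathwayDB, path) -> None:
    with open(path, "w") as handle:
        for pid in sorted(db.pathways):
            desc = db.names.get(pid, "")
            tokens = [f"{g}:{arr:g}" for g, arr in sorted(db.pathways[pid].items())]
            handle.write("\t".join([pid, desc, *tokens]) + "\n")


def read_plate_tsv(path) -> pd.DataFrame:
    """Plate table: columns well, role, concentration_uM, replicate, od."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"well", "role", "concentration_uM", "replicate", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing plate columns {sorted(missing)}")
    if (df["od"] < 0).any():
        raise ParseError(f"{path}: negative optical densities")
    return df


def read_events_tsv(path) -> pd.DataFrame:
    """Cytometry event table: event_id, av, pi [+ condition columns]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"av", "pi"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing event columns {sorted(missing)}")
    return df


def read_probe_matrix(probes_path, samples_path) -> ProbeMatrix:
    """Probe matrix TSV (probe_id, gene, one column per sample) + annotations."""
    raw = pd.read_csv(probes_path, sep="\t", comment="#")
    for col in ("probe_id", "gene"):
        if col not in raw.columns:
            raise ParseError(f"{probes_path}: missing column {col!r}")
    raw = raw.set_index("probe_id")
    samples = pd.read_csv(samples_path, sep="\t", comment="#").set_index("sample")
    missing = {"group", "concentration_uM", "replicate"} - set(samples.columns)
    if missing:
        raise ParseError(f"{samples_path}: missing annotation columns {sorted(missing)}")
    return ProbeMatrix(
        signals=raw.drop(columns=["gene"]),
        probe_to_gene=raw["gene"],
        samples=samples,
    )


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Deterministic TSV writer: fixed float format, stable column order."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_results(out_dir, pas: pd.DataFrame | None = None,
                  cnr: pd.DataFrame | None = None,
                  fits: list | None = None,
                  fractions: dict | None = None) -> list[Path]:
    """Write analysis outputs with deterministic ordering; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if pas is not None:
        p = out_dir / "pas.tsv"
        write_tsv(pas.sort_values(["pathway", "sample"]).reset_index(drop=True), p, index=False)
        written.append(p)
    if cnr is not None:
        p = out_dir / "cnr.tsv"
        write_tsv(cnr.sort_index().sort_index(axis=1), p)
        written.append(p)
    if fits is not None:
        p = out_dir / "fits.json"
        payload = [f.to_dict() for f in fits]
        p.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
        written.append(p)
    if fractions is not None:
        p = out_dir / "quadrants.tsv"
        rows = [{"condition": str(k), **v.as_dict(), "n_events": v.n_events}
                for k, v in sorted(fractions.items(), key=lambda kv: str(kv[0]))]
        write_tsv(pd.DataFrame(rows), p, index=False)
        written.append(p)
    return written


_CONFIG_KEYS = {
    "probes", "samples", "pathways", "plate", "events", "fasta", "out",
    "seed", "floor", "av_gate", "pi_gate", "time_tol", "conc_min_effect",
    "caspase_tol", "max_dose", "log_level", "wavelength_nm",
}


@dataclass
class RunConfig:
    """Validated run configuration loaded from YAML; unknown keys rejected."""

    values: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("probes", "samples", "pathways", "plate", "events", "fasta"):
            if key in data and not Path(data[key]).exists():
                raise ParseError(f"{path}: input path for {key!r} does not exist: {data[key]}")
        return cls(values=data)

    def get(self, key, default=None):
        return self.values.get(key, default)
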