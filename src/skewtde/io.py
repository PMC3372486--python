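"""File readers/writers and the end-to-end fit pipeline.

Formats: a probes x arrays expression TSV (first column probe IDs, header
row of array IDs), a two-column metadata TSV (array_id, group in {1, 2}),
YAML for simulation truths and run configs, TSV/JSON for fit outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ExpressionDataSet, log2_transform
from .design import build_design
from .inference import (
    call_differential_expression,
    compute_dic,
    summarize_hyperparameters,
)
from .model import ModelSpec
from .sampler import ChainSamples, run_chain
from .simulate import SimulationTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_dataset",
    "write_dataset",
    "read_truth_yaml",
    "write_truth_yaml",
    "RunConfig",
    "run_fit_command",
    "write_fit_outputs",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Parse a probes x arrays expression TSV into a DataFrame.

    First column holds probe IDs, the header row array IDs. Duplicate IDs,
    ragged rows and non-numeric cells are rejected with coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {ncol})"
                )
            ids.append(parts[0])
            rows.append(parts[1:])
    array_ids = header[1:]
    if not array_ids:
        raise ValueError(f"{path}: no array columns")
    for name, seq in (("probe", ids), ("array", array_ids)):
        dupes = pd.Index(seq)[pd.Index(seq).duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"{path}: duplicated {name} identifiers: {dupes}")
    values = np.empty((len(ids), len(array_ids)))
    for r, row in enumerate(rows):
        for c, cell in enumerate(row):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                values[r, c] = np.nan
                continue
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at probe {ids[r]!r}, "
                    f"array {array_ids[c]!r}"
                ) from None
    return pd.DataFrame(values, index=pd.Index(ids, name="probe_id"),
                        columns=array_ids)


def write_expression_tsv(path, ds: ExpressionDataSet) -> None:
    ds.to_frame().rename_axis("probe_id").to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Two-column (array_id, group) table; group labels must be 1 or 2."""
    meta = pd.read_csv(path, sep="\t", dtype={"array_id": str})
    required = {"array_id", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    return meta


def write_metadata_tsv(path, ds: ExpressionDataSet) -> None:
    pd.DataFrame({"array_id": ds.array_ids, "group": ds.group}).to_csv(
        path, sep="\t", index=False
    )


def read_dataset(expression_path, metadata_path, log2: bool = False
                 ) -> ExpressionDataSet:
    """Join an expression TSV with its metadata into a validated dataset,
    optionally applying the base-2 log transform to raw intensities."""
    expr = read_expression_tsv(expression_path)
    meta = read_metadata_tsv(metadata_path)
    missing = set(expr.columns) - set(meta["array_id"])
    if missing:
        raise ValueError(f"arrays without metadata: {sorted(missing)}")
    groups = meta.set_index("array_id")["group"].astype(int)
    values = expr.to_numpy()
    if log2:
        values = log2_transform(values)
    return ExpressionDataSet(
        values=values,
        probe_ids=list(expr.index),
        array_ids=list(expr.columns),
        group=groups.loc[list(expr.columns)].to_numpy(),
    )


def write_dataset(outdir, ds: ExpressionDataSet,
                  prefix: str = "expression") -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = outdir / f"{prefix}.tsv"
    meta = outdir / f"{prefix}_metadata.tsv"
    write_expression_tsv(expr, ds)
    write_metadata_tsv(meta, ds)
    return expr, meta


def write_truth_yaml(path, truth: SimulationTruth) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)


def read_truth_yaml(path) -> SimulationTruth:
    with open(path) as fh:
        return SimulationTruth.from_dict(yaml.safe_load(fh))


@dataclass
class RunConfig:
    """Everything one fit run needs; round-trips losslessly through YAML."""

    expression: str
    metadata: str
    outdir: str
    spec: ModelSpec = field(default_factory=ModelSpec)
    log2: bool = False
    overwrite: bool = False
    progress_every: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = self.spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["spec"] = ModelSpec.from_dict(d["spec"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _prepare_outdir(outdir, overwrite: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{outdir} exists and is not empty; pass overwrite to reuse it"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def write_fit_outputs(outdir, samples: ChainSamples, design) -> dict:
    """Persist one fit: scalar trace, hyperparameter summary, DE table and
    DIC JSON. Returns the DIC record."""
    outdir = Path(outdir)
    samples.scalars.to_csv(outdir / "scalar_trace.tsv", sep="\t", index=False)
    summarize_hyperparameters(samples).to_csv(
        outdir / "hyperparameter_summary.tsv", sep="\t", index=False
    )
    probe = pd.DataFrame(
        dict(probe_id=samples.probe_ids,
             p_mean=samples.p_mean, p_sd=samples.p_sd,
             d_mean=samples.d_mean, d_sd=samples.d_sd)
    )
    probe.to_csv(outdir / "probe_summary.tsv", sep="\t", index=False)
    de = call_differential_expression(samples)
    de.table.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
    dic = compute_dic(samples, design)
    record = dict(model=dic.model, dbar=dic.dbar, dhat=dic.dhat,
                  pd=dic.pd, dic=dic.dic, n_significant=de.n_significant)
    with open(outdir / "dic.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return record


def run_fit_command(config: RunConfig) -> dict:
    """Full pipeline: read data -> (log2) -> design -> chain -> outputs.

    Writes a machine-readable run manifest (seed, versions, config hash)
    next to the outputs and returns the DIC record.
    """
    outdir = _prepare_outdir(config.outdir, config.overwrite)
    ds = read_dataset(config.expression, config.metadata, log2=config.log2)
    design = build_design(ds)
    samples = run_chain(design, config.spec, progress_every=config.progress_every)
    record = write_fit_outputs(outdir, samples, design)
    manifest = dict(
        tool="skewtde",
        version=__version__,
        python=platform.python_version(),
        numpy=np.__version__,
        seed=config.spec.seed,
        config=config.to_dict(),
        config_hash=config.config_hash(),
        n_probes=ds.n_probes,
        n_arrays=ds.n_arrays,
        group_sizes=list(ds.group_sizes),
        dic=record,
    )
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return record
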