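"""File formats: pair tables (TSV), genet manifests (JSON/YAML), trajectory
output, simulation configs, age reports, and a minimal two-sample VCF reader.

Conventions: all site coordinates are 1-based inclusive; readers reject
malformed input rather than coercing it; every artifact written by a run
carries a JSON metadata sidecar (parameters, seed, package version) from
which it can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import PAIR_COLUMNS, AgeEstimate, CalibrationModel, GenetSample, validate_pair_table
from .sim import (
    SeasonalQuiescence,
    SimulationParams,
    StochasticQuiescence,
    Trajectory,
)

__all__ = [
    "read_pair_table",
    "write_pair_table",
    "read_genet_manifest",
    "write_genet_sample",
    "read_vcf_pair_table",
    "params_from_mapping",
    "read_sim_config",
    "params_to_mapping",
    "write_trajectory",
    "read_trajectory",
    "write_metadata",
    "emit_report",
    "read_calibration_points",
    "write_calibration_model",
    "read_calibration_model",
]

_PairKey = Tuple[str, str]


def _check_overwrite(path: Union[str, Path], overwrite: bool) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    return path


# -- pair tables --------------------------------------------------------------

def read_pair_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a normal/tumor pair table (TSV).

    Header must be exactly the canonical columns; rows with non-integer
    counts, alt > depth, or duplicate sites are rejected with the offending
    line number.
    """
    path = Path(path)
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "site_chrom": str,
                "site_pos": np.int64,
                "normal_depth": np.int64,
                "normal_alt": np.int64,
                "tumor_depth": np.int64,
                "tumor_alt": np.int64,
            },
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed pair table: {exc}") from exc
    if list(table.columns) != PAIR_COLUMNS:
        raise ValueError(
            f"{path}: header must be {PAIR_COLUMNS}, got {list(table.columns)}"
        )
    try:
        return validate_pair_table(table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_pair_table(
    table: pd.DataFrame, path: Union[str, Path], overwrite: bool = False
) -> Path:
    path = _check_overwrite(path, overwrite)
    validate_pair_table(table).to_csv(path, sep="\t", index=False)
    return path


def read_vcf_pair_table(
    path: Union[str, Path], normal: str, tumor: str
) -> pd.DataFrame:
    """Pair table from a minimal two-sample VCF with AD-style depth fields.

    Uses the per-sample AD field (ref,alt read counts); depth is the AD sum.
    Requires pysam (optional dependency).
    """
    import pysam

    rows = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in (normal, tumor):
            if s not in samples:
                raise ValueError(f"{path}: sample {s!r} not in VCF ({samples})")
        for rec in vcf:
            out = {}
            for side, s in (("normal", normal), ("tumor", tumor)):
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) < 2 or any(x is None for x in ad[:2]):
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks AD for {s!r}"
                    )
                out[f"{side}_depth"] = int(sum(ad))
                out[f"{side}_alt"] = int(sum(ad[1:]))
            rows.append(
                (rec.chrom, rec.pos, out["normal_depth"], out["normal_alt"],
                 out["tumor_depth"], out["tumor_alt"])
            )
    table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return validate_pair_table(table)


# -- genet manifests ----------------------------------------------------------

def read_genet_manifest(path: Union[str, Path]) -> GenetSample:
    """Load a genet manifest (JSON or YAML) and all referenced pair tables.

    Schema::

        name: genet1
        genome_size: 10000000
        ramets: [{id: R01, size_e: 9800000}, ...]
        pair_tables: [{normal: R01, tumor: R02, path: tables/R01_R02.tsv}, ...]

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("ramets", "pair_tables", "genome_size"):
        if key not in doc:
            raise ValueError(f"{path}: manifest missing key {key!r}")
    size_e = {str(r["id"]): float(r["size_e"]) for r in doc["ramets"]}
    tables: Dict[_PairKey, pd.DataFrame] = {}
    for entry in doc["pair_tables"]:
        key = (str(entry["normal"]), str(entry["tumor"]))
        tables[key] = read_pair_table(path.parent / entry["path"])
    return GenetSample(
        ramets=list(size_e),
        pair_tables=tables,
        size_e=size_e,
        genome_size=float(doc["genome_size"]),
        name=str(doc.get("name", path.stem)),
    )


def write_genet_sample(
    genet: GenetSample, out_dir: Union[str, Path], overwrite: bool = False
) -> Path:
    """Write pair tables and a manifest for a genet; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for (normal, tumor), table in sorted(genet.pair_tables.items()):
        rel = f"{genet.name}_{normal}_{tumor}.tsv"
        write_pair_table(table, out_dir / rel, overwrite=overwrite)
        entries.append({"normal": normal, "tumor": tumor, "path": rel})
    manifest = {
        "name": genet.name,
        "genome_size": genet.genome_size,
        "ramets": [{"id": rm, "size_e": genet.size_e[rm]} for rm in genet.ramets],
        "pair_tables": entries,
    }
    mpath = _check_overwrite(out_dir / f"{genet.name}.manifest.json", overwrite)
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


# -- simulation config, trajectory, metadata ----------------------------------

def params_from_mapping(doc: Mapping) -> SimulationParams:
    """SimulationParams from a flat mapping mirroring the field names.

    ``quiescence`` may be null, ``{kind: stochastic, rate_in: .., rate_out: ..}``
    or ``{kind: seasonal, active_fraction: .., period: ..}``.
    """
    doc = dict(doc)
    q = doc.pop("quiescence", None)
    if q is not None:
        kind = q.pop("kind")
        if kind == "stochastic":
            q = StochasticQuiescence(**q)
        elif kind == "seasonal":
            q = SeasonalQuiescence(**q)
        else:
            raise ValueError(f"unknown quiescence kind {kind!r}")
    valid = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    params = SimulationParams(quiescence=q, **doc)
    params.validate()
    return params


def read_sim_config(path: Union[str, Path]) -> SimulationParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return params_from_mapping(doc)


def params_to_mapping(params: SimulationParams) -> dict:
    doc = dataclasses.asdict(params)
    q = params.quiescence
    if isinstance(q, StochasticQuiescence):
        doc["quiescence"] = {"kind": "stochastic", **dataclasses.asdict(q)}
    elif isinstance(q, SeasonalQuiescence):
        doc["quiescence"] = {"kind": "seasonal", **dataclasses.asdict(q)}
    if isinstance(doc.get("seed"), np.random.SeedSequence):
        doc["seed"] = None
    return doc


def write_metadata(
    path: Union[str, Path], params: Optional[SimulationParams] = None,
    seed: Optional[int] = None, extra: Optional[Mapping] = None,
    overwrite: bool = False,
) -> Path:
    """JSON sidecar from which a run's artifacts are reproducible."""
    meta = {"genetclock_version": __version__, "seed": seed}
    if params is not None:
        meta["params"] = params_to_mapping(params)
    if extra:
        meta.update(extra)
    path = _check_overwrite(path, overwrite)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def write_trajectory(
    traj: Trajectory, path: Union[str, Path], seed: Optional[int] = None,
    overwrite: bool = False,
) -> Path:
    """Trajectory TSV (time, module_id, fixed_count) + metadata sidecar."""
    path = _check_overwrite(path, overwrite)
    traj.to_frame().to_csv(path, sep="\t", index=False)
    write_metadata(
        Path(str(path) + ".meta.json"), params=traj.params, seed=seed,
        overwrite=overwrite,
    )
    return path


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    expected = ["time", "module_id", "fixed_count"]
    if list(t.columns) != expected:
        raise ValueError(f"{path}: header must be {expected}")
    if (t["fixed_count"] < 0).any():
        raise ValueError(f"{path}: negative fixed_count")
    return t


# -- reports ------------------------------------------------------------------

def _sig(x: float, digits: int = 6) -> float:
    return float(f"{x:.{digits}g}")


def emit_report(
    results: Mapping[str, AgeEstimate], path: Union[str, Path],
    model: Optional[CalibrationModel] = None, overwrite: bool = False,
) -> Tuple[Path, Path]:
    """Per-genet age report as JSON plus a combined TSV.

    Numbers are serialized to 6 significant digits.
    """
    path = _check_overwrite(path, overwrite)
    doc: dict = {"genetclock_version": __version__, "genets": {}}
    if model is not None:
        doc["model"] = {
            "slope": _sig(model.slope),
            "intercept": _sig(model.intercept),
            "r2_adj": _sig(model.r2_adj) if np.isfinite(model.r2_adj) else None,
            "n_points": model.n_points,
        }
    rows = []
    for name, est in results.items():
        d = {k: (_sig(v) if isinstance(v, float) else v) for k, v in est.to_dict().items()}
        doc["genets"][name] = d
        rows.append({"genet": name, **d})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    tsv_path = Path(str(path).removesuffix(".json") + ".tsv")
    cols = ["genet", "mean_vrf50", "mean_vrf50_ci_low", "mean_vrf50_ci_high",
            "age", "age_ci_low", "age_ci_high", "fixed_mutations", "clipped"]
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)
    return path, tsv_path


def read_calibration_points(path: Union[str, Path]) -> List[Tuple[float, float]]:
    """TSV with columns age, mean_vrf50 (one calibration genet per row)."""
    t = pd.read_csv(path, sep="\t")
    for col in ("age", "mean_vrf50"):
        if col not in t.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return list(zip(t["age"].astype(float), t["mean_vrf50"].astype(float)))


def write_calibration_model(
    model: CalibrationModel, path: Union[str, Path], overwrite: bool = False
) -> Path:
    path = _check_overwrite(path, overwrite)
    with open(path, "w") as fh:
        json.dump(
            {"slope": model.slope, "intercept": model.intercept,
             "r2_adj": model.r2_adj, "n_points": model.n_points},
            fh, indent=2,
        )
    return path


def read_calibration_model(path: Union[str, Path]) -> CalibrationModel:
    with open(path) as fh:
        doc = json.load(fh)
    return CalibrationModel(
        slope=float(doc["slope"]), intercept=float(doc["intercept"]),
        r2_adj=float(doc.get("r2_adj", float("nan"))),
        n_points=int(doc.get("n_points", 0)),
    )
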