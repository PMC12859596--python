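"""Validated readers and writers plus the run configuration.

File formats are plain text: long-format CSV (RFC-4180, UTF-8, header
row) for the stratified panel, covariates and expected counts; a
whitespace edge list with an ``n_areas`` header for the graph; and a
flat ``key = value`` file for run configuration.  Area identifiers are
opaque strings; internal indices are assigned by sorted order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CovariateMatrix, ExpectedCounts, StratifiedPanel
from .graph import AreaGraph, read_edge_list, write_edge_list
from .model import ModelSpec

__all__ = [
    "read_panel", "write_panel",
    "read_covariates", "write_covariates",
    "read_expected", "write_expected",
    "read_graph", "write_graph",
    "read_dataset", "write_dataset",
    "RunConfig",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def read_panel(path: str | Path) -> StratifiedPanel:
    df = pd.read_csv(path, dtype={"area_id": str})
    return StratifiedPanel(df)


def write_panel(panel: StratifiedPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_covariates(path: str | Path, restandardize: bool = True) -> CovariateMatrix:
    """Read area-level covariates; re-standardise (with a warning) if needed."""
    df = pd.read_csv(path, dtype={"area_id": str})
    if "area_id" not in df.columns:
        raise ValueError(f"{path}: covariate file needs an 'area_id' column")
    if df["area_id"].duplicated().any():
        dup = df["area_id"][df["area_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate area_id {dup!r}")
    df = df.sort_values("area_id", kind="stable").reset_index(drop=True)
    names = [c for c in df.columns if c != "area_id"]
    if not names:
        raise ValueError(f"{path}: no covariate columns")
    cov = CovariateMatrix(df[names].to_numpy(float), names, df["area_id"].tolist())
    if restandardize and not cov.is_standardized():
        logger.warning("%s: covariate columns were not standardised; re-standardising", path)
        cov = cov.standardize()
    return cov


def write_covariates(cov: CovariateMatrix, path: str | Path) -> None:
    ids = cov.area_ids or [str(i) for i in range(cov.n_areas)]
    df = pd.DataFrame(cov.values, columns=cov.names)
    df.insert(0, "area_id", ids)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_expected(path: str | Path) -> ExpectedCounts:
    df = pd.read_csv(path, dtype={"area_id": str})
    for col in ("area_id", "year", "expected"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected-counts file needs column {col!r}")
    area_ids = sorted(df["area_id"].unique())
    years = sorted(df["year"].unique())
    tab = df.set_index(["area_id", "year"])["expected"].unstack("year")
    return ExpectedCounts(tab.loc[area_ids, years].to_numpy(), area_ids, list(years))


def write_expected(e: ExpectedCounts, path: str | Path) -> None:
    e.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


read_graph = read_edge_list
write_graph = write_edge_list


def read_dataset(
    counts_path: str | Path,
    graph_path: str | Path,
    covariates_path: str | Path,
) -> tuple[StratifiedPanel, AreaGraph, CovariateMatrix]:
    """Read and cross-validate the three study inputs.

    Checks the complete stratum grid (done by the panel container), that
    the graph covers exactly the panel's areas, and that the covariate
    file carries one row per area in the same sorted-id order.
    """
    panel = read_panel(counts_path)
    graph = read_graph(graph_path)
    cov = read_covariates(covariates_path)
    if graph.n_areas != panel.n_areas:
        raise ValueError(
            f"graph has {graph.n_areas} areas but panel has {panel.n_areas}"
        )
    if cov.area_ids is not None:
        panel_ids = panel.area_ids
        unknown = sorted(set(cov.area_ids) - set(panel_ids))
        if unknown:
            raise ValueError(f"covariates contain unknown area id {unknown[0]!r}")
        missing = sorted(set(panel_ids) - set(cov.area_ids))
        if missing:
            raise ValueError(f"covariates missing area id {missing[0]!r}")
    return panel, graph, cov


def write_dataset(
    panel: StratifiedPanel,
    graph: AreaGraph,
    cov: CovariateMatrix,
    directory: str | Path,
) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.csv",
        "graph": directory / "graph.txt",
        "covariates": directory / "covariates.csv",
    }
    if cov.area_ids is None:
        cov = CovariateMatrix(cov.values, cov.names, panel.area_ids)
    write_panel(panel, paths["counts"])
    write_graph(graph, paths["graph"])
    write_covariates(cov, paths["covariates"])
    return paths


# ---------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    counts: str
    graph: str
    covariates: str
    outdir: str = "hurdlemap_out"
    seed: int = 0
    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    thin: int = 1
    cri: float = 0.95
    percentiles: int = 100
    spatial: bool = True
    temporal: bool = True
    interaction: bool = True
    share_free: bool = True
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    pc_u_phi: float = 0.5
    pc_alpha_phi: float = 0.5

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.chains < 2:
            raise ValueError("pipeline runs need at least 2 chains for diagnostics")
        if not (0.0 < self.cri < 1.0):
            raise ValueError("cri must lie in (0, 1)")
        if not (0 <= self.warmup < self.iterations):
            raise ValueError("need 0 <= warmup < iterations")
        for key in ("counts", "graph", "covariates"):
            path = Path(getattr(self, key))
            if not path.exists():
                raise FileNotFoundError(f"{key} file not found: {path}")

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            include_spatial=self.spatial,
            include_temporal=self.temporal,
            include_interaction=self.interaction,
            share_scales_free=self.share_free,
            pc_u=self.pc_u,
            pc_alpha=self.pc_alpha,
            pc_u_phi=self.pc_u_phi,
            pc_alpha_phi=self.pc_alpha_phi,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in self.to_dict().items():
                fh.write(f"{key} = {val}\n")

    @classmethod
    def read(cls, path: str | Path, **overrides) -> "RunConfig":
        values: dict = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: malformed config line {line!r}")
                key, raw = (s.strip() for s in line.split("=", 1))
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        parsed = {}
        for key, raw in values.items():
            if key not in fields:
                raise ValueError(f"{path}: unknown config key {key!r}")
            parsed[key] = _parse(raw, fields[key])
        return cls(**parsed)


def _parse(raw, annot):
    if not isinstance(raw, str):
        return raw
    t = str(annot)
    if "bool" in t:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if "int" in t:
        return int(raw)
    if "float" in t:
        return float(raw)
    return raw
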