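"""Parameter sweeps: ensembles across a swept axis with analytic overlays.

A sweep runs one ensemble per axis value (axis ``c``, ``n``, ``S`` or
``s``), summarizes it, and returns a tidy table with simulated statistics,
bootstrap standard errors, matching closed-form predictions where defined,
and the regime thresholds annotated per row.  Every sweep point runs on
its own seed substream, so rows are reproducible independently of
execution order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analytics
from .diversity import (
    BimodalityUndefinedError,
    afd_summary,
    bimodality_coefficient,
    diversity_summary,
    mean_pairwise_jaccard,
)
from .gillespie import assemble_ensemble
from .model import EnsembleResult, ModelParams, ParameterError, regime_thresholds, validate

__all__ = ["SweepSpec", "run_sweep", "run_preset", "effective_dispersal_view", "PRESETS"]

_AXES = ("c", "n", "S", "s")
_STATISTICS = ("bc", "mean_abundance", "dispersal_events", "richness", "jaccard")


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a base parameter set, a swept axis, and what to measure."""

    base: ModelParams
    axis: str
    values: tuple
    M: int
    root_seed: int
    statistics: tuple[str, ...] = ("bc", "mean_abundance", "dispersal_events")
    bootstrap: int = 1000

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}")
        if len(self.values) == 0:
            raise ValueError("value list must be nonempty")
        unknown = set(self.statistics) - set(_STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")
        object.__setattr__(self, "values", tuple(self.values))
        object.__setattr__(self, "statistics", tuple(self.statistics))

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "axis": self.axis,
            "values": list(self.values),
            "M": self.M,
            "root_seed": self.root_seed,
            "statistics": list(self.statistics),
            "bootstrap": self.bootstrap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        d = dict(d)
        d["base"] = ModelParams.from_dict(d["base"])
        d["values"] = tuple(d["values"])
        if "statistics" in d:
            d["statistics"] = tuple(d["statistics"])
        return cls(**d)


def _point_params(base: ModelParams, axis: str, value) -> ModelParams:
    if axis == "c":
        return validate(dataclasses.replace(base, c=float(value)))
    if axis == "n":
        return validate(dataclasses.replace(base, n=int(value)))
    if axis == "S":
        S = int(value)
        r = float(np.mean(base.r))
        return validate(
            dataclasses.replace(base, S=S, p=(1.0 / S,) * S, r=(r,) * S)
        )
    # axis == "s": vary rB = rA - s at fixed rA (two-species pools)
    if base.S != 2:
        raise ParameterError("axis 's' requires a two-species pool")
    rA = base.r[0]
    return validate(dataclasses.replace(base, r=(rA, rA - float(value))))


def _point_seed(root_seed: int, j: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence(root_seed, spawn_key=(j, salt))
    return int(ss.generate_state(1)[0])


def _bootstrap_se_bc(x: np.ndarray, B: int, rng: np.random.Generator) -> float:
    M = x.size
    vals = np.empty(B)
    for b in range(B):
        sample = x[rng.integers(0, M, size=M)]
        try:
            vals[b] = bimodality_coefficient(sample)
        except BimodalityUndefinedError:
            vals[b] = np.nan
    return float(np.nanstd(vals, ddof=1))


def _bootstrap_se_jaccard(ensemble: EnsembleResult, B: int, rng: np.random.Generator) -> float:
    # resample communities; mean over pairs of a weighted resample is
    # w^T D w / (M (M-1)) since the distance matrix has zero diagonal
    P = (ensemble.counts_matrix() > 0).astype(np.float64)
    inter = P @ P.T
    rich = P.sum(axis=1)
    union = rich[:, None] + rich[None, :] - inter
    D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    M = ensemble.M
    W = rng.multinomial(M, np.full(M, 1.0 / M), size=B).astype(np.float64)
    stats_b = np.einsum("ij,bj->bi", D, W)
    stats_b = np.einsum("bi,bi->b", W, stats_b) / (M * (M - 1))
    return float(np.std(stats_b, ddof=1))


def _se(values: np.ndarray) -> float:
    """Standard error of the mean; NaN for fewer than 2 values."""
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _measure_point(spec: SweepSpec, j: int, value) -> dict:
    params = _point_params(spec.base, spec.axis, value)
    seed = _point_seed(spec.root_seed, j)
    boot_rng = np.random.default_rng(np.random.SeedSequence(spec.root_seed, spawn_key=(j, 1)))
    c_low, c_high = regime_thresholds(params)
    row: dict = {
        "axis": spec.axis,
        "value": value,
        "c": params.c,
        "n": params.n,
        "S": params.S,
        "pA": params.p[0],
        "K": params.K,
        "M": spec.M,
        "seed": seed,
        "c_low_threshold": c_low,
        "c_high_threshold": c_high,
        "error": "",
    }
    if params.S == 2:
        row["s"] = params.s
    ensemble = assemble_ensemble(params, spec.M, seed)
    r_mean = float(np.mean(params.r))

    if "bc" in spec.statistics:
        afd = afd_summary(ensemble, focal=0)
        row["bc"] = afd.bc if afd.bc_defined else np.nan
        row["bc_se"] = (
            _bootstrap_se_bc(afd.abundances, spec.bootstrap, boot_rng)
            if afd.bc_defined
            else np.nan
        )
        row["bc_pred_low"] = (
            analytics.bc_low_dispersal(params.n, params.p[0])
            if params.S == 2 and 0.0 < params.p[0] < 1.0
            else np.nan
        )
        row["bc_pred_high"] = analytics.bc_high_dispersal()
    if "mean_abundance" in spec.statistics:
        x = ensemble.counts_matrix()[:, 0] / params.K
        row["mean_rel_abundance"] = float(x.mean())
        row["mean_rel_abundance_se"] = _se(x)
        if params.S == 2:
            row["mean_rel_abundance_pred_low"] = (
                analytics.mean_abundance_low_dispersal(
                    params.s, params.p[0], params.K, params.n
                )
                / params.K
            )
    if "dispersal_events" in spec.statistics:
        ev = ensemble.dispersal_events().astype(float)
        im = ensemble.immigrants().astype(float)
        row["mean_dispersal_events"] = float(ev.mean())
        row["mean_dispersal_events_se"] = _se(ev)
        row["mean_immigrants"] = float(im.mean())
        row["mean_immigrants_se"] = _se(im)
        row["mcluster_pred"] = (
            analytics.mean_contributing_clusters(params.c, r_mean, params.K, params.n)
            if params.c > 0
            else np.nan
        )
    if "richness" in spec.statistics:
        div = diversity_summary(ensemble)
        row["mean_richness"] = div.mean_richness
        row["mean_richness_se"] = _se(div.richness_values.astype(float))
        row["richness_pred_low"] = analytics.richness_pmf(params.n, params.S).mean
    if "jaccard" in spec.statistics:
        row["mean_jaccard"] = mean_pairwise_jaccard(ensemble)
        row["mean_jaccard_se"] = _bootstrap_se_jaccard(ensemble, spec.bootstrap, boot_rng)
        row["jaccard_pred_low"] = analytics.mean_jaccard(params.n, params.S)
    return row


def run_sweep(spec: SweepSpec, progress=None) -> pd.DataFrame:
    """Run every sweep point; per-point failures are recorded in the row's
    ``error`` column and the sweep continues."""
    rows = []
    for j, value in enumerate(spec.values):
        try:
            row = _measure_point(spec, j, value)
        except Exception as err:  # noqa: BLE001 - failures stay in-row
            row = {
                "axis": spec.axis,
                "value": value,
                "M": spec.M,
                "seed": _point_seed(spec.root_seed, j),
                "error": f"{type(err).__name__}: {err}",
            }
        rows.append(row)
        if progress is not None:
            progress(j, len(spec.values), value)
    return pd.DataFrame(rows)


def effective_dispersal_view(table: pd.DataFrame) -> pd.DataFrame:
    """Re-key a c-sweep table by the effective dispersal rate ``n * c``
    (individuals arriving per unit time rather than clusters).  Idempotent."""
    out = table.copy()
    out["effective_dispersal"] = out["n"] * out["c"]
    return out.sort_values("effective_dispersal", kind="stable").reset_index(drop=True)


# -- presets ---------------------------------------------------------------

_C_GRID = tuple(float(x) for x in np.logspace(-4, 4, 9))
_LOW_C = 1e-4


def _preset_cluster_contributions(K, M, root_seed, neutral_r=1.0):
    """Mean contributing clusters and immigrants vs dispersal rate."""
    specs = []
    for i, n in enumerate((1, 10, 100)):
        base = ModelParams(S=2, p=(0.5, 0.5), r=(neutral_r, neutral_r), c=_LOW_C, n=n, K=K)
        specs.append(
            SweepSpec(
                base=base,
                axis="c",
                values=_C_GRID,
                M=M,
                root_seed=_point_seed(root_seed, i, salt=100),
                statistics=("dispersal_events",),
            )
        )
    return specs


def _preset_bimodality(K, M, root_seed):
    """Bimodality coefficient vs dispersal rate for several cluster sizes."""
    specs = []
    for i, n in enumerate((1, 2, 10, 100)):
        base = ModelParams(S=2, p=(0.5, 0.5), r=(1.0, 1.0), c=_LOW_C, n=n, K=K)
        specs.append(
            SweepSpec(
                base=base,
                axis="c",
                values=_C_GRID,
                M=M,
                root_seed=_point_seed(root_seed, i, salt=101),
                statistics=("bc", "mean_abundance"),
            )
        )
    return specs


def _preset_selection(K, M, root_seed):
    """Mean relative abundance vs cluster size under selection (s = -0.05),
    low-dispersal regime."""
    base = ModelParams(S=2, p=(0.5, 0.5), r=(1.0, 1.05), c=_LOW_C, n=1, K=K)
    return [
        SweepSpec(
            base=base,
            axis="n",
            values=(1, 2, 5, 10, 20, 50),
            M=M,
            root_seed=_point_seed(root_seed, 0, salt=102),
            statistics=("mean_abundance", "bc"),
        )
    ]


def _preset_multispecies(K, M, root_seed, S=7):
    """Richness and Jaccard distance vs dispersal rate, S equally abundant
    neutral species."""
    specs = []
    for i, n in enumerate((1, 5, 10)):
        base = ModelParams(S=S, p=(1.0 / S,) * S, r=(1.0,) * S, c=_LOW_C, n=n, K=K)
        specs.append(
            SweepSpec(
                base=base,
                axis="c",
                values=_C_GRID,
                M=M,
                root_seed=_point_seed(root_seed, i, salt=103),
                statistics=("richness", "jaccard"),
            )
        )
    return specs


PRESETS = {
    "cluster-contributions": _preset_cluster_contributions,
    "bimodality-vs-dispersal": _preset_bimodality,
    "selection-vs-cluster-size": _preset_selection,
    "multispecies-diversity": _preset_multispecies,
}


def run_preset(
    name: str,
    *,
    root_seed: int = 0,
    K: int = 1000,
    M: int = 1000,
    paper_scale: bool = False,
    progress=None,
) -> pd.DataFrame:
    """Run a named preset and concatenate its sweeps into one table.

    Default scale (K=10^3, M=10^3) preserves the K-insensitive statistics
    at a fraction of the cost; ``paper_scale=True`` switches to K=10^5,
    M=10^4.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    if paper_scale:
        K, M = 100_000, 10_000
    frames = [run_sweep(spec, progress=progress) for spec in PRESETS[name](K, M, root_seed)]
    return pd.concat(frames, ignore_index=True)


def write_sweep(table: pd.DataFrame, path: str, spec: SweepSpec | None = None) -> None:
    """Write a sweep table as TSV, with a JSON provenance sidecar if the
    spec is given."""
    table.to_csv(path, sep="\t", index=False)
    if spec is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(spec.to_dict(), fh, indent=1)


def read_sweep(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
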