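"""Parameter and state containers for the cluster-dispersal assembly model.

The model describes the de-novo assembly of a local microbial community
from an infinite, fixed species pool.  Clusters of ``n`` individuals arrive
at rate ``c`` with composition drawn from the pool frequencies ``p``;
resident individuals of species ``i`` replicate at rate ``r[i]``; both
processes are damped by the logistic saturation factor ``(1 - N/K)`` and
assembly ends the first time the community size ``N`` reaches the carrying
capacity ``K``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "CommunityState",
    "EnsembleResult",
    "ParameterError",
    "validate",
    "regime_thresholds",
    "two_species",
]

#: sum(p) must equal 1 to within this tolerance
_P_TOL = 1e-12


class ParameterError(ValueError):
    """A model parameter violates one of the documented invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one assembly scenario.

    Parameters
    ----------
    S : int
        Number of species in the pool (>= 1).
    p : tuple of float
        Pool relative abundances, length ``S``, summing to 1.  For two
        species this is ``(pA, 1 - pA)``.
    r : tuple of float
        Per-species replication rates (1/time), all > 0.
    c : float
        Dispersal rate of clusters (1/time), >= 0.
    n : int
        Cluster size, in ``[1, K]`` (fixed-size mode; in random mode the
        mean of the cluster-size distribution).
    K : int
        Carrying capacity, >= 2.
    d : float
        Per-capita death rate (1/time), default 0 (robustness variant).
    saturate_dispersal : bool
        Whether the ``(1 - N/K)`` factor multiplies the dispersal
        propensity (default True; False is the no-saturation variant in
        which dispersal proceeds at rate ``c`` regardless of crowding).
    cluster_size_mode : str
        ``"fixed"`` (every cluster has exactly ``n`` individuals) or
        ``"random"`` (zero-truncated Poisson sizes with rate ``n``).
    """

    S: int
    p: tuple[float, ...]
    r: tuple[float, ...]
    c: float
    n: int
    K: int
    d: float = 0.0
    saturate_dispersal: bool = True
    cluster_size_mode: str = "fixed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", int(self.S))
        object.__setattr__(self, "p", tuple(float(x) for x in np.atleast_1d(self.p)))
        object.__setattr__(self, "r", tuple(float(x) for x in np.atleast_1d(self.r)))
        object.__setattr__(self, "c", float(self.c))
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "K", int(self.K))
        object.__setattr__(self, "d", float(self.d))

    @property
    def pA(self) -> float:
        """Pool abundance of the first (focal) species."""
        return self.p[0]

    @property
    def s(self) -> float:
        """Selection coefficient ``s = rA - rB`` (two-species pools only)."""
        if self.S != 2:
            raise ParameterError("selection coefficient s is defined for S=2 only")
        return self.r[0] - self.r[1]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["p"] = list(self.p)
        d["r"] = list(self.r)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


def two_species(
    pA: float,
    rA: float = 1.0,
    rB: float = 1.0,
    *,
    c: float,
    n: int,
    K: int,
    **kwargs,
) -> ModelParams:
    """Convenience constructor for the two-species pool ``(pA, 1 - pA)``."""
    return validate(ModelParams(S=2, p=(pA, 1.0 - pA), r=(rA, rB), c=c, n=n, K=K, **kwargs))


def validate(params: ModelParams) -> ModelParams:
    """Check every invariant of ``params``; return it unchanged if valid.

    Raises :class:`ParameterError` naming the violated invariant.
    Idempotent: ``validate(validate(p)) == validate(p)``.
    """
    if params.S < 1:
        raise ParameterError("species count S must be >= 1")
    if len(params.p) != params.S:
        raise ParameterError(f"pool vector p has length {len(params.p)}, expected S={params.S}")
    if len(params.r) != params.S:
        raise ParameterError(f"rate vector r has length {len(params.r)}, expected S={params.S}")
    if any(x < 0 for x in params.p):
        raise ParameterError("pool abundances must be non-negative")
    if abs(math.fsum(params.p) - 1.0) > _P_TOL:
        raise ParameterError("pool abundances must sum to 1")
    if any(x <= 0 for x in params.r):
        raise ParameterError("replication rates must be > 0")
    if params.c < 0:
        raise ParameterError("dispersal rate c must be >= 0")
    if params.d < 0:
        raise ParameterError("death rate d must be >= 0")
    if params.K < 2:
        raise ParameterError("carrying capacity K must be >= 2")
    if params.n < 1:
        raise ParameterError("cluster size must be >= 1")
    if params.n > params.K:
        raise ParameterError(f"cluster size n={params.n} exceeds carrying capacity K={params.K}")
    if params.cluster_size_mode not in ("fixed", "random"):
        raise ParameterError("cluster_size_mode must be 'fixed' or 'random'")
    return params


def regime_thresholds(params: ModelParams) -> tuple[float, float]:
    """Dispersal-rate thresholds separating the assembly regimes.

    Returns ``(c_low, c_high) = (r / (2 ln K), r)`` with ``r`` the mean
    replication rate.  Below ``c_low`` assembly is replication-dominated
    (the first cluster typically grows to ``K`` before a second arrives);
    above ``c_high`` dispersal outpaces replication.
    """
    if params.K <= 1:
        raise ParameterError("carrying capacity K must exceed 1")
    r = float(np.mean(params.r))
    return r / (2.0 * math.log(params.K)), r


@dataclass
class CommunityState:
    """Species counts and event counters of one (partially) assembled community."""

    counts: np.ndarray
    t: float = 0.0
    n_dispersal_events: int = 0
    n_immigrants: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def N(self) -> int:
        """Total community size."""
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        """Number of species present (strictly positive counts)."""
        return int(np.count_nonzero(self.counts))


@dataclass
class EnsembleResult:
    """Final states of ``M`` replicate communities under one parameter set."""

    params: ModelParams
    M: int
    final_states: list[CommunityState]
    root_seed: int

    def counts_matrix(self) -> np.ndarray:
        """(M, S) integer matrix of final per-species abundances."""
        return np.array([s.counts for s in self.final_states], dtype=np.int64)

    def dispersal_events(self) -> np.ndarray:
        return np.array([s.n_dispersal_events for s in self.final_states], dtype=np.int64)

    def immigrants(self) -> np.ndarray:
        return np.array([s.n_immigrants for s in self.final_states], dtype=np.int64)

    # -- tabular round trip ------------------------------------------------

    def to_tsv(self, path: str) -> None:
        """Write final counts (one row per community) as TSV with a JSON sidecar."""
        import pandas as pd

        df = pd.DataFrame(
            self.counts_matrix(), columns=[f"species_{i}" for i in range(self.params.S)]
        )
        df["t"] = [s.t for s in self.final_states]
        df["n_dispersal_events"] = self.dispersal_events()
        df["n_immigrants"] = self.immigrants()
        df.to_csv(path, sep="\t", index=False)
        sidecar = {"params": self.params.to_dict(), "M": self.M, "root_seed": self.root_seed}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str) -> "EnsembleResult":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        params = ModelParams.from_dict(sidecar["params"])
        count_cols = [f"species_{i}" for i in range(params.S)]
        states = [
            CommunityState(
                counts=row[count_cols].to_numpy(dtype=np.int64),
                t=float(row["t"]),
                n_dispersal_events=int(row["n_dispersal_events"]),
                n_immigrants=int(row["n_immigrants"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(
            params=params, M=int(sidecar["M"]), final_states=states, root_seed=int(sidecar["root_seed"])
        )
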