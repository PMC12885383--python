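"""Exact stochastic simulation of single-community assembly.

Implements the standard exact stochastic simulation algorithm for the
three event types — replication of each species, arrival of a dispersing
cluster, and (optionally) per-capita death.  Assembly terminates the first
time the community size reaches the carrying capacity ``K`` exactly; a
cluster that would overshoot ``K`` is thinned by sampling the accepted
individuals without replacement from its drawn composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CommunityState, EnsembleResult, ModelParams, validate

__all__ = [
    "EventRecord",
    "AssemblyError",
    "draw_cluster",
    "propensities",
    "assemble_community",
    "assemble_ensemble",
]


class AssemblyError(RuntimeError):
    """Assembly did not complete within the event budget."""


@dataclass(frozen=True)
class EventRecord:
    """One realized event: its kind, occurrence time, and count increments.

    ``kind`` is ``"replication_i"`` or ``"death_i"`` (``i`` the species
    index) or ``"dispersal"``.  ``delta_counts`` sums to +1 for
    replication, -1 for death, and to the accepted cluster size for
    dispersal.
    """

    kind: str
    t: float
    delta_counts: tuple[int, ...]


def _cluster_size(params: ModelParams, rng: np.random.Generator) -> int:
    """Cluster size: ``n`` in fixed mode, zero-truncated Poisson(n) in random mode."""
    if params.cluster_size_mode == "fixed":
        return params.n
    while True:  # rejection is cheap: P(0) = exp(-n)
        size = int(rng.poisson(params.n))
        if size > 0:
            return size


def draw_cluster(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one cluster composition from the pool.

    For a two-species pool the count of species A is Binomial(n, pA); in
    general the composition is Multinomial(n, p).  Returns an integer
    vector of length ``S`` summing to the cluster size.
    """
    size = _cluster_size(params, rng)
    if params.S == 1:
        return np.array([size], dtype=np.int64)
    if params.S == 2:
        a = rng.binomial(size, params.p[0])
        return np.array([a, size - a], dtype=np.int64)
    return rng.multinomial(size, params.p).astype(np.int64)


def propensities(state: CommunityState, params: ModelParams) -> np.ndarray:
    """Event propensities in the order (replication_0..S-1, dispersal, death_0..S-1).

    Replication of species ``i`` proceeds at ``r[i] * (1 - N/K) * N_i``,
    dispersal at ``c * (1 - N/K)`` (or plain ``c`` without saturation),
    and death at ``d * N_i``.  All are zero-bounded; replication and
    saturated dispersal vanish at ``N = K``.
    """
    N = state.N
    if N > params.K:
        raise AssemblyError(f"internal truncation bug: N={N} exceeds K={params.K}")
    sat = 1.0 - N / params.K
    rep = np.asarray(params.r) * sat * state.counts
    disp = params.c * sat if params.saturate_dispersal else params.c
    death = params.d * np.asarray(state.counts, dtype=float)
    return np.concatenate([rep, [disp], death])


def assemble_community(
    params: ModelParams,
    rng: np.random.Generator | int,
    *,
    record_events: bool = False,
    max_events: int | None = None,
) -> tuple[CommunityState, list[EventRecord] | None]:
    """Assemble one community from empty until ``N = K``.

    The next event is chosen with probability proportional to its
    propensity and the waiting time is exponential with the total
    propensity.  With the default saturated dynamics the shared
    ``(1 - N/K)`` factor cancels in the selection step, so final-state
    statistics depend only on the embedded jump chain; times are still
    recorded.

    Parameters
    ----------
    params : ModelParams
    rng : numpy Generator or integer seed
    record_events : bool
        If True, also return the full event log.
    max_events : int, optional
        Event budget; default ``1000 * K``.  Exceeding it (possible only
        in the death variant) raises :class:`AssemblyError`.
    """
    params = validate(params)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    S, K = params.S, params.K
    r = params.r
    c, d = params.c, params.d
    saturate = params.saturate_dispersal
    if max_events is None:
        max_events = 1000 * K

    counts = [0] * S
    N = 0
    t = 0.0
    disp_events = 0
    immigrants = 0
    log: list[EventRecord] | None = [] if record_events else None
    exponential = rng.exponential
    random = rng.random

    n_events = 0
    while N < K:
        n_events += 1
        if n_events > max_events:
            raise AssemblyError(
                f"assembly did not complete within {max_events} events (N={N} of K={K})"
            )
        sat = 1.0 - N / K
        rep = [r[i] * sat * counts[i] for i in range(S)]
        disp = c * sat if saturate else c
        total = sum(rep) + disp
        if d > 0.0:
            dea = [d * counts[i] for i in range(S)]
            total += sum(dea)
        if total <= 0.0:
            raise AssemblyError(
                "no event has positive propensity (c=0 with an empty community?)"
            )
        t += exponential() / total

        u = random() * total
        acc = 0.0
        chosen = None  # (kind, species index or None)
        for i in range(S):
            acc += rep[i]
            if u < acc:
                chosen = ("replication", i)
                break
        if chosen is None:
            acc += disp
            if u < acc or d <= 0.0:
                chosen = ("dispersal", None)
            else:
                for i in range(S):
                    acc += dea[i]
                    if u < acc:
                        chosen = ("death", i)
                        break
                else:  # numerical edge: assign to the last positive entry
                    chosen = ("dispersal", None)

        kind, i = chosen
        if kind == "replication":
            counts[i] += 1
            N += 1
            if log is not None:
                delta = [0] * S
                delta[i] = 1
                log.append(EventRecord(f"replication_{i}", t, tuple(delta)))
        elif kind == "death":
            counts[i] -= 1
            N -= 1
            if log is not None:
                delta = [0] * S
                delta[i] = -1
                log.append(EventRecord(f"death_{i}", t, tuple(delta)))
        else:
            comp = draw_cluster(params, rng)
            size = int(comp.sum())
            if N + size > K:
                # hypergeometric thinning keeps exactly K - N individuals
                comp = rng.multivariate_hypergeometric(comp, K - N)
                size = K - N
            for j in range(S):
                counts[j] += int(comp[j])
            N += size
            disp_events += 1
            immigrants += size
            if log is not None:
                log.append(EventRecord("dispersal", t, tuple(int(x) for x in comp)))

    state = CommunityState(
        counts=np.array(counts, dtype=np.int64),
        t=t,
        n_dispersal_events=disp_events,
        n_immigrants=immigrants,
    )
    return state, log


def write_event_log(records: list[EventRecord], path: str) -> None:
    """Write an event log as tab-separated records (t, kind, delta_counts)."""
    with open(path, "w") as fh:
        fh.write("t\tkind\tdelta_counts\n")
        for rec in records:
            delta = ",".join(str(x) for x in rec.delta_counts)
            fh.write(f"{rec.t:.12g}\t{rec.kind}\t{delta}\n")


def assemble_ensemble(
    params: ModelParams,
    M: int,
    root_seed: int,
    *,
    max_events: int | None = None,
) -> EnsembleResult:
    """Assemble ``M`` independent replicate communities.

    Replicate ``k`` runs on the substream spawned from
    ``SeedSequence(root_seed)`` at index ``k``, so results are bit-exact
    under the same ``root_seed`` and insensitive to execution order.
    """
    if M < 1:
        raise ValueError("ensemble size M must be >= 1")
    params = validate(params)
    children = np.random.SeedSequence(root_seed).spawn(M)
    states = []
    for k, child in enumerate(children):
        try:
            state, _ = assemble_community(
                params, np.random.default_rng(child), max_events=max_events
            )
        except AssemblyError as err:
            raise AssemblyError(f"replicate {k}: {err}") from err
        states.append(state)
    return EnsembleResult(params=params, M=M, final_states=states, root_seed=int(root_seed))
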