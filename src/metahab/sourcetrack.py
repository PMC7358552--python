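"""Bayesian microbial source tracking by collapsed Gibbs sampling.

Each read of a sink community is assigned a latent source environment
(one of the designated sources or an extra "Unknown" source).  The
collapsed Gibbs conditional for read ``n`` of taxon ``t`` is

    P(z_n = v | .) ~ (m_tv + alpha_v) / (m_.v + alpha_v * T) * (n_v^-n + beta)

where for known sources ``m`` counts the source's reads plus the sink reads
currently assigned to it (prior ``alpha_known``), for the unknown source
``m`` counts only currently assigned sink reads (prior ``alpha_unknown``),
``T`` is the number of taxa and ``n_v^-n`` the sink reads assigned to ``v``
excluding read ``n``.  Mixing proportions are posterior means of the
assignment fractions over retained sweeps, pooled across random restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .model import OtuTable, ValidationError, rarefy, spawn_seeds

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"


@dataclass
class SourceEstimate:
    sink_id: str
    proportions: dict[str, float]  # includes "Unknown"; sums to 1
    draws: np.ndarray  # retained posterior draws, (n_draws, n_sources+1)
    credible_intervals: dict[str, tuple[float, float]]  # central 95%


@njit(cache=True)
def _gibbs_chain(
    read_taxa,  # (N,) taxon index per sink read
    source_counts,  # (V, T) known-source taxon counts
    alpha_known,
    alpha_unknown,
    beta_prior,
    burnin,
    n_draws,
    delay,
    seed,
):
    np.random.seed(seed)
    n_reads = read_taxa.shape[0]
    n_known, n_taxa = source_counts.shape
    n_env = n_known + 1  # last index is Unknown
    source_tot = np.zeros(n_known)
    for v in range(n_known):
        source_tot[v] = source_counts[v].sum()

    z = np.empty(n_reads, dtype=np.int64)
    env_n = np.zeros(n_env)  # sink reads per environment
    assigned = np.zeros((n_env, n_taxa))  # sink reads per (env, taxon)
    for n in range(n_reads):
        v = np.random.randint(0, n_env)
        z[n] = v
        env_n[v] += 1.0
        assigned[v, read_taxa[n]] += 1.0

    draws = np.zeros((n_draws, n_env))
    probs = np.empty(n_env)
    kept = 0
    sweep = 0
    while kept < n_draws:
        sweep += 1
        for n in range(n_reads):
            v_old = z[n]
            t = read_taxa[n]
            env_n[v_old] -= 1.0
            assigned[v_old, t] -= 1.0
            total = 0.0
            for v in range(n_env):
                if v < n_known:
                    num = source_counts[v, t] + assigned[v, t] + alpha_known
                    den = source_tot[v] + env_n[v] + alpha_known * n_taxa
                else:
                    num = assigned[v, t] + alpha_unknown
                    den = env_n[v] + alpha_unknown * n_taxa
                p = (num / den) * (env_n[v] + beta_prior)
                probs[v] = p
                total += p
            u = np.random.random() * total
            acc = 0.0
            v_new = n_env - 1
            for v in range(n_env):
                acc += probs[v]
                if u <= acc:
                    v_new = v
                    break
            z[n] = v_new
            env_n[v_new] += 1.0
            assigned[v_new, t] += 1.0
        if sweep > burnin and (sweep - burnin) % delay == 0:
            for v in range(n_env):
                draws[kept, v] = env_n[v] / n_reads
            kept += 1
    return draws


def source_track(
    sink: np.ndarray,
    sources: dict[str, np.ndarray],
    alpha_known: float = 0.001,
    alpha_unknown: float = 0.1,
    beta_prior: float = 10.0,
    restarts: int = 10,
    burnin: int = 100,
    draws_per_restart: int = 10,
    delay: int = 10,
    seed: int | None = None,
    sink_id: str = "sink",
) -> SourceEstimate:
    """Estimate the mixing proportions of one sink over known sources + Unknown.

    ``sink`` is a taxon count vector; ``sources`` maps labels to pooled
    count vectors over the same taxa.  Returns posterior-mean proportions,
    retained draws and central 95% credible intervals.
    """
    sink = np.asarray(sink)
    if sink.sum() == 0:
        raise ValidationError("empty sink")
    if not sources:
        raise ValidationError("need >= 1 source")
    if min(alpha_known, alpha_unknown) <= 0 or beta_prior <= 0:
        raise ValidationError("priors must be positive")
    labels = list(sources)
    src = np.vstack([np.asarray(sources[s], dtype=float) for s in labels])
    if src.shape[1] != sink.shape[0]:
        raise ValidationError("sink and sources must share one taxa index")
    read_taxa = np.repeat(np.arange(sink.shape[0]), sink.astype(np.int64))
    chain_seeds = spawn_seeds(seed if seed is not None else 0, restarts)
    all_draws = []
    for cs in chain_seeds:
        all_draws.append(
            _gibbs_chain(
                read_taxa,
                src,
                float(alpha_known),
                float(alpha_unknown),
                float(beta_prior),
                int(burnin),
                int(draws_per_restart),
                int(delay),
                int(cs),
            )
        )
    draws = np.vstack(all_draws)
    mean = draws.mean(axis=0)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    names = labels + [UNKNOWN]
    return SourceEstimate(
        sink_id=sink_id,
        proportions={s: float(m) for s, m in zip(names, mean)},
        draws=draws,
        credible_intervals={s: (float(a), float(b)) for s, a, b in zip(names, lo, hi)},
    )


def leave_one_habitat_out(
    table: OtuTable,
    meta: pd.DataFrame,
    sink_depth: int = 1000,
    seed: int | None = None,
    **gibbs_settings,
) -> dict[str, pd.DataFrame]:
    """Source-track every habitat's samples against the remaining habitats.

    For each habitat H, each sample of H is a sink (rarefied to
    ``sink_depth`` reads for tractability; shallower sinks are kept as-is)
    and every other habitat's samples are pooled by summed counts into one
    source profile.  Returns, per habitat, a frame of per-sink proportions
    whose last row ``mean`` is the habitat summary.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    habitats = list(dict.fromkeys(meta["habitat"]))
    if len(habitats) < 2:
        raise ValidationError("need >= 2 habitats for source tracking")
    s_rare, s_gibbs = spawn_seeds(seed if seed is not None else 0, 2)
    df = table.to_dataframe()
    pooled = {h: df.loc[meta.index[meta["habitat"] == h]].sum(axis=0).to_numpy() for h in habitats}
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        totals = table.sample_totals()
        deep = [s for s, t in zip(table.sample_ids, totals) if t >= sink_depth]
        rarefied = (
            rarefy(table.select_samples(deep), sink_depth, seed=s_rare) if deep else None
        )
    results: dict[str, pd.DataFrame] = {}
    sink_seeds = spawn_seeds(s_gibbs, len(meta))
    k = 0
    for h in habitats:
        sink_ids = list(meta.index[meta["habitat"] == h])
        if not sink_ids:
            logger.warning("habitat %r has no samples; skipped", h)
            continue
        sources = {g: pooled[g] for g in habitats if g != h}
        rows = {}
        for sid in sink_ids:
            if rarefied is not None and sid in rarefied.sample_ids:
                sink = rarefied.sample_vector(sid)
            else:
                sink = table.sample_vector(sid)
            est = source_track(
                sink, sources, seed=sink_seeds[k], sink_id=sid, **gibbs_settings
            )
            rows[sid] = est.proportions
            k += 1
        frame = pd.DataFrame(rows).T
        frame.loc["mean"] = frame.mean(axis=0)
        results[h] = frame
    return results
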