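"""Bayesian mixture-model source apportionment of sink communities.

A Knights-style collapsed Gibbs sampler assigns every sink read to one of
the known source environments or to an "Unknown" source.  Source taxon
profiles enter as Dirichlet-smoothed count vectors that are updated by the
reads currently assigned to them; mixing proportions get a Dirichlet prior
scaled by sink depth (alpha1 for known sources, alpha2 for the unknown).
Posterior mean proportions are averaged over post-burn-in sweeps and over
independent restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .containers import CommunityMatrix
from .diversity import rarefy
from .errors import InvalidArgumentError, SchemaError

UNKNOWN = "Unknown"


@njit(cache=True)
def _gibbs_kernel(read_taxa, m_vt, m_v, alpha1, alpha2, beta, n_burnin, n_draws, seed):
    """One chain of collapsed Gibbs; returns per-sweep proportion draws."""
    np.random.seed(seed)
    n_reads = read_taxa.size
    n_src = m_v.size  # known sources
    n_all = n_src + 1
    n_taxa = m_vt.shape[1]

    z = np.empty(n_reads, dtype=np.int64)
    n_v = np.zeros(n_all)
    n_vt = np.zeros((n_all, n_taxa))
    for i in range(n_reads):
        v = np.random.randint(0, n_all)
        z[i] = v
        n_v[v] += 1.0
        n_vt[v, read_taxa[i]] += 1.0

    draws = np.zeros((n_draws, n_all))
    probs = np.empty(n_all)
    for sweep in range(n_burnin + n_draws):
        for i in range(n_reads):
            t = read_taxa[i]
            v_old = z[i]
            n_v[v_old] -= 1.0
            n_vt[v_old, t] -= 1.0
            total = 0.0
            for v in range(n_all):
                if v < n_src:
                    like = (m_vt[v, t] + n_vt[v, t] + beta) / (m_v[v] + n_v[v] + n_taxa * beta)
                    prior = n_v[v] + alpha1 * n_reads
                else:
                    like = (n_vt[v, t] + beta) / (n_v[v] + n_taxa * beta)
                    prior = n_v[v] + alpha2 * n_reads
                probs[v] = prior * like
                total += probs[v]
            u = np.random.random() * total
            acc = 0.0
            v_new = n_all - 1
            for v in range(n_all):
                acc += probs[v]
                if u <= acc:
                    v_new = v
                    break
            z[i] = v_new
            n_v[v_new] += 1.0
            n_vt[v_new, t] += 1.0
        if sweep >= n_burnin:
            for v in range(n_all):
                draws[sweep - n_burnin, v] = n_v[v] / n_reads
    return draws


@dataclass
class SourceEstimate:
    sink_id: str
    proportions: dict[str, float]
    credible_intervals: dict[str, tuple[float, float]]
    n_draws: int


def _collapse_sources(sources: CommunityMatrix, source_labels: dict[str, str]) -> pd.DataFrame:
    unknown_ids = set(sources.sample_ids) - set(source_labels)
    if unknown_ids:
        raise SchemaError(f"source samples without an environment label: {sorted(unknown_ids)}")
    lab = pd.Series({s: source_labels[s] for s in sources.sample_ids})
    return sources.counts.groupby(lab).sum()


def estimate_sources(
    sinks: CommunityMatrix,
    sources: CommunityMatrix,
    source_labels: dict[str, str],
    n_burnin: int = 100,
    n_draws: int = 100,
    alpha1: float = 0.001,
    alpha2: float = 0.001,
    beta: float = 0.01,
    seed: int = 0,
    n_restarts: int = 10,
    rarefaction_depth: int | str | None = "min",
) -> dict[str, SourceEstimate]:
    """Posterior source proportions (plus Unknown) per sink community.

    ``source_labels`` maps source sample ids to environment names; samples
    of one environment are pooled into a single source profile.  Sinks are
    rarefied to a common depth first (``'min'`` = smallest sink library;
    ``None`` disables).  Deterministic given the seed.
    """
    if min(alpha1, alpha2, beta) <= 0:
        raise InvalidArgumentError("priors must be positive")
    if list(sinks.taxon_ids) != list(sources.taxon_ids):
        raise SchemaError("sinks and sources must share one taxon universe (same columns)")

    nonempty = [s for s in sinks.sample_ids if sinks.counts.loc[s].sum() > 0]
    for s in sinks.sample_ids:
        if s not in nonempty:
            warnings.warn(f"empty sink {s!r} skipped")
    sinks = sinks.subset_samples(nonempty)
    if rarefaction_depth is not None:
        sinks = rarefy(sinks, depth=rarefaction_depth, seed=seed)

    profile = _collapse_sources(sources, source_labels)
    env_names = list(profile.index)
    m_vt = profile.to_numpy(dtype=np.float64)
    m_v = m_vt.sum(axis=1)

    results: dict[str, SourceEstimate] = {}
    for si, sink_id in enumerate(sinks.sample_ids):
        counts = sinks.counts.loc[sink_id].to_numpy(dtype=np.int64)
        read_taxa = np.repeat(np.arange(counts.size), counts).astype(np.int64)
        all_draws = []
        for r in range(n_restarts):
            chain_seed = (seed * 100003 + si * 613 + r * 7 + 1) % (2**31 - 1)
            all_draws.append(
                _gibbs_kernel(
                    read_taxa, m_vt, m_v,
                    float(alpha1), float(alpha2), float(beta),
                    int(n_burnin), int(n_draws), chain_seed,
                )
            )
        draws = np.vstack(all_draws)
        mean = draws.mean(axis=0)
        lo = np.percentile(draws, 2.5, axis=0)
        hi = np.percentile(draws, 97.5, axis=0)
        names = env_names + [UNKNOWN]
        results[sink_id] = SourceEstimate(
            sink_id=sink_id,
            proportions={n: float(mean[i]) for i, n in enumerate(names)},
            credible_intervals={n: (float(lo[i]), float(hi[i])) for i, n in enumerate(names)},
            n_draws=int(draws.shape[0]),
        )
    return results


def estimates_as_frame(estimates: dict[str, SourceEstimate]) -> pd.DataFrame:
    """Sink x source proportion table."""
    return pd.DataFrame({s: e.proportions for s, e in estimates.items()}).T.rename_axis("sink_id")


def niche_chain_sources(
    matrix: CommunityMatrix,
    metadata: pd.DataFrame,
    niche_order,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Source-track each niche against all upstream niches along the continuum.

    For every niche after the first, the samples of that niche are sinks and
    the pooled samples of the upstream niches are sources; returns the mean
    proportion per (sink niche, source niche) with an Unknown column.
    """
    meta = metadata.set_index("sample_id")
    rows = []
    for k in range(1, len(niche_order)):
        sink_niche = niche_order[k]
        upstream = list(niche_order[:k])
        sink_ids = [s for s in matrix.sample_ids if meta.loc[s, "niche"] == sink_niche]
        src_ids = [s for s in matrix.sample_ids if meta.loc[s, "niche"] in upstream]
        sinks = matrix.subset_samples(sink_ids)
        sources = matrix.subset_samples(src_ids)
        labels = {s: str(meta.loc[s, "niche"]) for s in src_ids}
        est = estimate_sources(sinks, sources, labels, seed=seed + k, **kwargs)
        mean_props = estimates_as_frame(est).mean()
        for src, val in mean_props.items():
            rows.append((sink_niche, src, float(val)))
    return pd.DataFrame(rows, columns=["sink_niche", "source", "mean_proportion"])
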