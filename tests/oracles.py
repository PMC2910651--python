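"""Independent reference implementations used to validate the fast paths.

These deliberately use different algorithms from the package code: the
cluster-score oracle enumerates chains of candidate sites (equivalent to
maximizing over all non-overlapping site subsets with the window trimmed to
the subset's span), and the order-statistic oracle is plain Monte Carlo.
"""

from __future__ import annotations

import itertools

import numpy as np

from crmrank.pwm import Pwm
from crmrank.scoring import BackgroundModel, ClusterModel, site_log_odds


def candidate_sites(model: ClusterModel, bg: BackgroundModel, sequence: str):
    """All positive-scoring (start, end, score) sites, best strand per locus.

    Opposite-strand matches of one motif at one offset occupy the same
    coordinates, so only the better strand can ever be selected.
    """
    sites = []
    for pwm in model.motifs:
        w = pwm.length
        for o in range(len(sequence) - w + 1):
            window = sequence[o : o + w]
            s = max(
                site_log_odds(pwm, bg, window, "+"),
                site_log_odds(pwm, bg, window, "-"),
            )
            if s > 0 and s != float("-inf"):
                sites.append((o, o + w, s))
    return sites


def chain_cluster_score(model: ClusterModel, bg: BackgroundModel, sequence: str) -> float:
    """Max over all non-overlapping site subsets of
    sum(site scores) - gap_penalty * (inter-site gap bases), floored at 0."""
    sites = candidate_sites(model, bg, sequence)
    g = model.gap_penalty_bits_per_base
    sites.sort()
    n = len(sites)
    # f[i] = best chain value starting with site i
    f = [0.0] * n
    for i in range(n - 1, -1, -1):
        start_i, end_i, s_i = sites[i]
        best_tail = 0.0
        for j in range(i + 1, n):
            start_j = sites[j][0]
            if start_j >= end_i:
                tail = f[j] - g * (start_j - end_i)
                if tail > best_tail:
                    best_tail = tail
        f[i] = s_i + best_tail
    return max([0.0] + f)


def subset_cluster_score(model: ClusterModel, bg: BackgroundModel, sequence: str) -> float:
    """Literal enumeration over every subset (exponential; tiny cases only)."""
    sites = candidate_sites(model, bg, sequence)
    g = model.gap_penalty_bits_per_base
    best = 0.0
    for k in range(1, len(sites) + 1):
        for combo in itertools.combinations(sites, k):
            combo = sorted(combo)
            if any(a[1] > b[0] for a, b in zip(combo, combo[1:])):
                continue  # overlapping
            span = combo[-1][1] - combo[0][0]
            covered = sum(e - s for s, e, _ in combo)
            val = sum(s for _, _, s in combo) - g * (span - covered)
            best = max(best, val)
    return best


def mc_order_statistic_q(
    ratios: np.ndarray, sorted_uniform_draws: np.ndarray
) -> tuple[float, float]:
    """Monte-Carlo joint-order-statistic probability and its standard error.

    ``sorted_uniform_draws`` has shape (n_draws, N), each row N uniforms
    sorted ascending.
    """
    hit = (sorted_uniform_draws <= np.asarray(ratios)[None, :]).all(axis=1)
    p = hit.mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / len(hit))
    return float(p), float(se)


def random_motif(rng: np.random.Generator, width: int, motif_id: str = "m") -> Pwm:
    counts = np.round(rng.dirichlet([0.7] * 4, size=width) * 60) + 1
    return Pwm.from_counts(motif_id, counts)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
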