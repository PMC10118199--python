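"""Outcome statistics of noise-evolution runs.

Turns evolution records into the quantities used to relate network position
to selection on expression noise:

* per-gene population expression variance and its relative change between
  the first and last generation, (var_1 - var_T) / (var_1 + var_T) — a
  value in [-1, 1], positive when variance was reduced;
* gene-level selective pressure — the average reduction of the mean
  intrinsic-noise parameter relative to its starting level, over the
  recorded generations; genes with pressure > 0.5 are called responsive;
* plug-in mutual information with equal-frequency binning and a Monte
  Carlo permutation p-value (optionally permuting within groups such as
  network ids).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .evolution import EvolutionRecord
from .rng import substream

__all__ = [
    "expression_variance",
    "relative_variance_change",
    "selective_pressure",
    "equal_frequency_bins",
    "mutual_information",
    "mi_permutation_test",
    "build_gene_table",
]


def expression_variance(population_states: np.ndarray) -> np.ndarray:
    """Per-gene sample variance (ddof=1) across individuals."""
    states = np.asarray(population_states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 2:
        raise ValueError("need an (N, n) matrix with N >= 2 individuals")
    return states.var(axis=0, ddof=1)


def relative_variance_change(var_first, var_last):
    """(var_first - var_last) / (var_first + var_last); NaN when both zero.

    Accepts scalars or arrays; positive values mean variance was reduced.
    """
    var_first = np.asarray(var_first, dtype=float)
    var_last = np.asarray(var_last, dtype=float)
    total = var_first + var_last
    zero = total == 0
    if np.any(zero):
        warnings.warn("relative variance change undefined where both variances are 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, np.nan, (var_first - var_last) / np.where(zero, 1, total))
    return float(out) if out.ndim == 0 else out


def selective_pressure(
    eta_trajectory: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Average normalized reduction of the mean noise parameter.

    ``eta_trajectory`` holds the per-generation (recorded-grid) population
    mean eta of one gene, starting at generation 1.  The pressure is the
    mean over recorded generations after the first of
    (eta_bar(1) - eta_bar(g)) / eta_bar(1); the zero generation-1 term is
    excluded.  ``responsive`` is strict: pressure > threshold.
    """
    traj = np.asarray(eta_trajectory, dtype=float)
    if traj.ndim != 1 or traj.size < 2:
        raise ValueError("need a 1-D trajectory with at least 2 recorded generations")
    start = traj[0]
    if start <= 0:
        raise ValueError("starting mean eta must be positive")
    pressure = float(np.mean((start - traj[1:]) / start))
    return pressure, pressure > threshold


def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin indices; ties broken by stable rank order."""
    x = np.asarray(x)
    n = x.size
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * bins) // n


def _resolve_bins(n: int, bins) -> int:
    if bins == "auto":
        return int(np.ceil(n ** (1.0 / 3.0)))
    return int(bins)


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mutual_information(x: np.ndarray, y: np.ndarray, bins="auto") -> float:
    """Plug-in mutual information (nats) of equal-frequency-binned data.

    Both variables are discretized into ceil(len^(1/3)) equal-frequency
    bins under ``bins='auto'``.  MI >= 0; MI(x, x) equals the entropy of
    the binned variable.  A constant input yields MI = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    for name, v in (("x", x), ("y", y)):
        if np.all(v == v[0]):
            warnings.warn(f"{name} is constant; mutual information is 0")
            return 0.0
    k = _resolve_bins(x.size, bins)
    bx = equal_frequency_bins(x, k)
    by = equal_frequency_bins(y, k)
    counts = np.zeros((k, k))
    np.add.at(counts, (bx, by), 1)
    return _mi_from_counts(counts)


def mi_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10_000,
    seed=0,
    group_labels=None,
    bins="auto",
) -> dict:
    """Monte Carlo permutation p-value for the mutual information.

    ``y`` is shuffled (within ``group_labels`` when given, e.g. within each
    network topology) and p = (1 + #{MI_perm >= MI_obs}) / (1 + B).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = substream(seed) if not isinstance(seed, np.random.Generator) else seed
    k = _resolve_bins(x.size, bins)
    bx = equal_frequency_bins(x, k)
    by = equal_frequency_bins(y, k)

    def mi_of(perm_by):
        counts = np.zeros((k, k))
        np.add.at(counts, (bx, perm_by), 1)
        return _mi_from_counts(counts)

    observed = mi_of(by)
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        groups = [np.nonzero(group_labels == g)[0] for g in np.unique(group_labels)]
    exceed = 0
    perm = by.copy()
    for _ in range(n_permutations):
        if group_labels is None:
            perm = rng.permutation(by)
        else:
            for idx in groups:
                perm[idx] = by[idx][rng.permutation(idx.size)]
        if mi_of(perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return {
        "mi": observed,
        "p_value": p,
        "n_permutations": n_permutations,
        "bins": k,
        "seed": seed if isinstance(seed, int) else None,
    }


def build_gene_table(
    records: dict,
    strengths: dict,
    masks: dict,
    pressure_threshold: float = 0.5,
) -> pd.DataFrame:
    """Assemble the per-(network, gene) outcome table.

    Parameters
    ----------
    records:
        network id -> list of :class:`EvolutionRecord` replicates (one
        selection mode per call).
    strengths:
        network id -> strengths DataFrame from :func:`node_strengths`.
    masks:
        network id -> boolean intermediate-expression mask; genes with a
        False mask (steady state at an expression bound) are excluded.

    Replicate aggregation: variances, relative change and selective
    pressure are averaged across replicates first; responsiveness is then
    the thresholded replicate-mean pressure.
    """
    if set(records) != set(strengths) or set(records) != set(masks):
        raise ValueError("network ids of records, strengths and masks must match")
    rows = []
    for net_id in records:
        reps = records[net_id]
        if not reps:
            raise ValueError(f"no replicates for network {net_id!r}")
        sdf = strengths[net_id].set_index("gene")
        mask = np.asarray(masks[net_id], dtype=bool)
        n = mask.size
        var1 = np.mean([r.var_expression[0] for r in reps], axis=0)
        varT = np.mean([r.var_expression[-1] for r in reps], axis=0)
        relchange = np.mean(
            [relative_variance_change(r.var_expression[0], r.var_expression[-1])
             for r in reps],
            axis=0,
        )
        pressures = np.mean(
            [[selective_pressure(r.mean_eta[:, i])[0] for i in range(n)] for r in reps],
            axis=0,
        )
        for i in range(n):
            if not mask[i]:
                continue
            rows.append(
                {
                    "network": net_id,
                    "gene": i,
                    "instrength": float(sdf.loc[i, "instrength"]),
                    "outstrength": float(sdf.loc[i, "outstrength"]),
                    "variance_gen1": float(var1[i]),
                    "variance_final": float(varT[i]),
                    "relative_variance_change": float(relchange[i]),
                    "selective_pressure": float(pressures[i]),
                    "responsive": bool(pressures[i] > pressure_threshold),
                    "intermediate_expression": True,
                }
            )
    return pd.DataFrame(rows)
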