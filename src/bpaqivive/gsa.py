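"""Two-phase global sensitivity analysis: Morris screening then eFAST.

Morris elementary-effects screening ranks all parameters cheaply; the
variance-based extended Fourier Amplitude Sensitivity Test (eFAST) then
decomposes output variance over the top-ranked subset into first-order (main,
S_M) and total-order (S_T) indices.  Because the Morris test is stochastic,
the final ranking is the mode over several repeats.  ``lowry_bounds``
produces the interaction ribbon (cumulative S_M lower bound, min-cumulative
S_T upper bound) used in Lowry plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

ModelFn = Callable[[Mapping[str, float]], float]


def _check_ranges(ranges: Mapping[str, tuple[float, float]]) -> list[str]:
    names = list(ranges)
    for n in names:
        lo, hi = ranges[n]
        if not lo < hi:
            raise DomainError(f"range for {n!r} must have lower < upper")
    return names


def _eval_matrix(model_fn, names, X):
    """Evaluate the model on rows of the unit-hypercube design X (scaled)."""
    out = []
    for row in X:
        try:
            y = model_fn({n: v for n, v in zip(names, row)})
        except Exception as exc:
            raise RuntimeError(
                f"model evaluation failed at {dict(zip(names, row))}") from exc
        out.append(np.atleast_1d(np.asarray(y, dtype=float)))
    return np.vstack(out)


def morris_elementary_effects(model_fn: ModelFn,
                              ranges: Mapping[str, tuple[float, float]],
                              trajectories: int = 50, levels: int = 8,
                              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """One Morris screen: mu_star and sigma of the elementary effects.

    Trajectory design on a ``levels``-level grid with the standard jump
    ``delta = levels / (2 (levels - 1))`` in unit-cube coordinates.
    """
    if trajectories < 4:
        raise DomainError("trajectories must be >= 4")
    names = _check_ranges(ranges)
    k = len(names)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(levels) / (levels - 1)
    base_levels = grid[grid <= 1.0 - delta + 1e-12]

    ee = [[] for _ in range(k)]
    for _ in range(trajectories):
        x = rng.choice(base_levels, size=k)
        order = rng.permutation(k)
        signs = rng.choice([-1.0, 1.0], size=k)
        pts = [x.copy()]
        for j in order:
            x = x.copy()
            step = delta * signs[j]
            if not (0.0 <= x[j] + step <= 1.0):
                step = -step
                signs[j] = -signs[j]
            x[j] += step
            pts.append(x)
        X = lo + np.array(pts) * (hi - lo)
        Y = _eval_matrix(model_fn, names, X)[:, 0]
        for pos, j in enumerate(order):
            ee[j].append((Y[pos + 1] - Y[pos]) / (delta * signs[j]))
    mu_star = np.array([np.mean(np.abs(e)) for e in ee])
    sigma = np.array([np.std(e) for e in ee])
    return pd.DataFrame({"parameter": names, "mu_star": mu_star, "sigma": sigma})


def morris_rank(model_fn: ModelFn, ranges: Mapping[str, tuple[float, float]],
                trajectories: int = 50, levels: int = 8, repeats: int = 6,
                seed: int = 0, top_k: int = 10) -> pd.DataFrame:
    """Repeated Morris screening; final rank is the mode across repeats.

    Rank 1 is the most influential parameter (largest mu_star).  Ties in the
    per-parameter rank mode are broken by the mean rank.  The returned table
    is sorted by final rank and flags the ``top_k`` selection.
    """
    if repeats < 1:
        raise DomainError("repeats must be >= 1")
    names = _check_ranges(ranges)
    rng = np.random.default_rng(seed)
    rank_rows = []
    mu_rows = []
    for _ in range(repeats):
        df = morris_elementary_effects(model_fn, ranges, trajectories, levels, rng)
        order = np.argsort(-df["mu_star"].to_numpy(), kind="stable")
        rank = np.empty(len(names), dtype=int)
        rank[order] = np.arange(1, len(names) + 1)
        rank_rows.append(rank)
        mu_rows.append(df["mu_star"].to_numpy())
    ranks = np.array(rank_rows)         # repeats x k
    mode_rank = []
    for j in range(len(names)):
        vals, counts = np.unique(ranks[:, j], return_counts=True)
        mode_rank.append(vals[np.argmax(counts)])
    out = pd.DataFrame({
        "parameter": names,
        "rank_mode": mode_rank,
        "rank_mean": ranks.mean(axis=0),
        "mu_star_mean": np.mean(mu_rows, axis=0),
    })
    out = out.sort_values(["rank_mode", "rank_mean"], kind="stable").reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    out["selected"] = out["final_rank"] <= top_k
    return out


@dataclass
class SensitivityResult:
    """eFAST indices; ``main`` and ``total`` are (n_params, n_outputs)."""

    parameters: list[str]
    main: np.ndarray
    total: np.ndarray
    degenerate: bool = False

    def to_frame(self, output_labels: Sequence | None = None) -> pd.DataFrame:
        rows = []
        n_out = self.main.shape[1]
        labels = output_labels if output_labels is not None else list(range(n_out))
        for j, lab in enumerate(labels):
            for i, p in enumerate(self.parameters):
                rows.append({"output": lab, "parameter": p,
                             "S_M": self.main[i, j], "S_T": self.total[i, j]})
        return pd.DataFrame(rows)


def efast(model_fn: ModelFn, ranges: Mapping[str, tuple[float, float]],
          samples_per_param: int = 1025, interference: int = 4,
          seed: int = 0, resamplings: int = 1) -> SensitivityResult:
    """eFAST first-order and total-order indices.

    One search curve per parameter: the parameter of interest is assigned the
    highest drive frequency and all complementary parameters low frequencies;
    the Fourier spectrum of the model output along the curve yields the main
    effect (power at the drive frequency and harmonics) and the total effect
    (one minus the power below half the drive frequency).  ``resamplings``
    averages the indices over several random-phase search curves, which
    damps the single-curve estimator noise.  Handles vector outputs (one
    index set per output component).
    """
    names = _check_ranges(ranges)
    k = len(names)
    if k < 2:
        raise DomainError("eFAST needs at least two parameters")
    ns = int(samples_per_param)
    M = int(interference)
    if ns < 4 * M**2 + 1:
        raise DomainError("samples_per_param too small for the interference factor")
    if ns % 2 == 0:
        ns += 1
    rng = np.random.default_rng(seed)
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])

    omega_max = (ns - 1) // (2 * M)
    m = max(omega_max // (2 * M), 1)
    if m >= k - 1:
        others = np.floor(np.linspace(1, m, k - 1)).astype(int)
    else:
        others = np.arange(k - 1) % m + 1

    s = (2.0 * np.pi / ns) * np.arange(ns)
    main = None
    total = None
    for i in range(k):
        acc_m = acc_t = None
        for _ in range(max(resamplings, 1)):
            omega = np.empty(k)
            omega[i] = omega_max
            omega[np.arange(k) != i] = others
            phi = rng.uniform(0, 2 * np.pi, size=k)
            X = 0.5 + np.arcsin(np.sin(omega[None, :] * s[:, None] + phi[None, :])) / np.pi
            Y = _eval_matrix(model_fn, names, lo + X * (hi - lo))   # ns x n_out
            if main is None:
                main = np.zeros((k, Y.shape[1]))
                total = np.zeros((k, Y.shape[1]))
                acc_m = np.zeros(Y.shape[1])
                acc_t = np.zeros(Y.shape[1])
            elif acc_m is None:
                acc_m = np.zeros(Y.shape[1])
                acc_t = np.zeros(Y.shape[1])
            F = np.fft.rfft(Y - Y.mean(axis=0), axis=0)
            spec = (np.abs(F) ** 2) / ns**2 * 2.0      # power per frequency
            V = spec[1:].sum(axis=0)
            harmonics = np.arange(1, M + 1) * omega_max
            D1 = spec[harmonics].sum(axis=0)
            Dc = spec[1:omega_max // 2 + 1].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                acc_m += np.where(V > 0, D1 / V, 0.0)
                acc_t += np.where(V > 0, np.clip(1.0 - Dc / V, 0.0, 1.0), 0.0)
        main[i] = acc_m / max(resamplings, 1)
        total[i] = acc_t / max(resamplings, 1)
    degenerate = bool(np.all(total <= 1e-12))
    if degenerate:
        main[:] = 0.0
        total[:] = 0.0
    return SensitivityResult(parameters=names, main=main, total=total,
                             degenerate=degenerate)


def lowry_bounds(result: SensitivityResult, output: int = 0) -> pd.DataFrame:
    """Interaction ribbon for a Lowry plot.

    Parameters are sorted by descending total effect; the ribbon at position
    p is bounded below by the cumulative main effects and above by
    min(cumulative total effects, 1).
    """
    sm = result.main[:, output]
    st = result.total[:, output]
    order = np.argsort(-st, kind="stable")
    names = [result.parameters[i] for i in order]
    cum_sm = np.cumsum(sm[order])
    upper = np.minimum(np.cumsum(st[order]), 1.0)
    lower = np.minimum(cum_sm, upper)
    return pd.DataFrame({"parameter": names, "S_M": sm[order], "S_T": st[order],
                         "cum_S_M": lower, "cum_S_T_capped": upper})


def lowry_plot(result: SensitivityResult, output: int = 0, ax=None, title=""):
    """Render the stacked main-effect/interaction bars with the ribbon."""
    import matplotlib.pyplot as plt

    df = lowry_bounds(result, output)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(df))
    ax.bar(x, df["S_M"], color="seagreen", label="main effect $S_M$")
    ax.bar(x, df["S_T"] - df["S_M"], bottom=df["S_M"], color="peru",
           label="interaction $S_T - S_M$")
    ax.fill_between(x, df["cum_S_M"], df["cum_S_T_capped"], alpha=0.3,
                    color="lightblue", label="interaction ribbon")
    ax.set_xticks(x, df["parameter"], rotation=90)
    ax.set_ylabel("proportion of variance")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper left", fontsize=8)
    if title:
        ax.set_title(title)
    return ax
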