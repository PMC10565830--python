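"""Reblocking (blocking analysis) standard errors for correlated series.

Potential-energy snapshots from MD are strongly autocorrelated, so the naive
standard error s/sqrt(n) underestimates the true uncertainty of the mean.
Pairwise reblocking repeatedly averages adjacent non-overlapping pairs of
values; once the block size exceeds the correlation length the block means
are effectively independent and the blocked standard error is unbiased.

Two selection rules are provided for reading a single number off the
blocking curve:

``max``
    the conservative rule used as the package default: take the largest SEM
    estimate over the reliable blocking levels.  The SEM estimate at a level
    with m blocks carries a relative uncertainty of 1/sqrt(2(m-1)), so
    levels with very few blocks are pure noise and would dominate an
    unrestricted maximum; the rule therefore only considers levels whose
    SEM is determined to 10% or better (m >= 50 blocks by default,
    tunable via ``min_blocks``), falling back to all levels with at least
    two blocks for very short series.
``heuristic``
    an optimal-block-size criterion: at each level estimate the correlation
    length from the statistical inefficiency, n_corr = (sem_B / sem_0)**2,
    and accept the smallest block size B with B**3 >= 2 * n * n_corr**2,
    falling back to ``max`` when no level qualifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy_io import TrajectoryEnsemble

__all__ = ["BlockingLevel", "BlockingCurve", "reblock", "select_sem", "ensemble_sem"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockingLevel:
    """Summary statistics of one blocking level."""

    block_size: int  # B = 2**k snapshots per block
    n_blocks: int  # m = floor(n / B)
    block_mean: float  # mean of the m block values (kcal/mol)
    sem_estimate: float  # sqrt(s^2 / m), s^2 unbiased variance of block values
    sem_of_sem: float  # sem_estimate / sqrt(2 (m - 1))


@dataclass(frozen=True)
class BlockingCurve:
    """SEM as a function of block size, with a selected uncertainty.

    Notes
    -----
    Odd leftover points are discarded at each pairwise-averaging step, so
    ``n_blocks`` at level k equals ``floor(n / 2**k)``.  The block mean is
    exactly invariant across levels only when n is a power of two; otherwise
    discarded tail points perturb it by O(1/n).
    """

    n: int
    levels: tuple
    n_corr: float
    selected_level: int
    selected_sem: float
    strategy: str

    @property
    def sem_estimates(self) -> np.ndarray:
        return np.array([lv.sem_estimate for lv in self.levels])


def _blocking_levels(series: np.ndarray) -> list[BlockingLevel]:
    levels = []
    x = series
    while len(x) >= 2:
        m = len(x)
        var = float(np.var(x, ddof=1))
        sem = float(np.sqrt(var / m))
        levels.append(
            BlockingLevel(
                block_size=2 ** len(levels),
                n_blocks=m,
                block_mean=float(np.mean(x)),
                sem_estimate=sem,
                sem_of_sem=sem / np.sqrt(2.0 * (m - 1)),
            )
        )
        if m < 4:
            break
        if m % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    return levels


#: Smallest number of blocks whose SEM estimate is trusted by the ``max``
#: rule: m = 50 keeps the relative uncertainty 1/sqrt(2(m-1)) at or below 10%.
DEFAULT_MIN_BLOCKS = 50


def reblock(series: Sequence[float], strategy: str = "max",
            min_blocks: int = DEFAULT_MIN_BLOCKS) -> BlockingCurve:
    """Pairwise reblocking of a scalar series.

    Level 0 holds the raw series; level k+1 averages adjacent
    non-overlapping pairs of level-k values, discarding a trailing odd
    element.  Each level reports sem = sqrt(s^2/m) with s^2 the unbiased
    sample variance over its m block values, and levels stop once fewer
    than two blocks remain.

    Parameters
    ----------
    series:
        Energy values (kcal/mol); length >= 4.
    strategy:
        Selection rule, ``"max"`` (default) or ``"heuristic"``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < 4:
        raise ValueError(f"reblocking needs at least 4 points, got {len(x)}")
    levels = _blocking_levels(x)
    idx, sem, n_corr = _select(levels, len(x), strategy, min_blocks)
    return BlockingCurve(
        n=len(x),
        levels=tuple(levels),
        n_corr=n_corr,
        selected_level=idx,
        selected_sem=sem,
        strategy=strategy,
    )


def _select(levels, n: int, strategy: str, min_blocks: int = DEFAULT_MIN_BLOCKS):
    sems = np.array([lv.sem_estimate for lv in levels])
    sem0 = sems[0]
    if strategy == "max":
        reliable = [k for k, lv in enumerate(levels) if lv.n_blocks >= min_blocks]
        if not reliable:  # short series: consider every level with >= 2 blocks
            reliable = list(range(len(levels)))
        idx = reliable[int(np.argmax(sems[reliable]))]
    elif strategy == "heuristic":
        # n_corr at each level from the statistical inefficiency
        # (sem_B / sem_0)^2; accept the smallest block size with
        # B^3 >= 2 n n_corr^2 (the optimal-block-size convention).
        idx = None
        for k, lv in enumerate(levels):
            ncorr_k = (lv.sem_estimate / sem0) ** 2 if sem0 > 0 else 0.0
            if lv.block_size**3 >= 2.0 * n * ncorr_k**2:
                idx = k
                break
        if idx is None:
            logger.warning(
                "no blocking level satisfies the optimal-block-size criterion; "
                "falling back to the conservative maximum"
            )
            idx, _, _ = _select(levels, n, "max", min_blocks)
    else:
        raise ValueError(f"unknown selection strategy {strategy!r}")
    sem = float(sems[idx])
    n_corr = float((sem / sem0) ** 2) if sem0 > 0 else 1.0
    return idx, sem, n_corr


def select_sem(curve: BlockingCurve, strategy: str = "max",
               min_blocks: int = DEFAULT_MIN_BLOCKS) -> float:
    """Selected uncertainty (kcal/mol) for a blocking curve under a rule."""
    _, sem, _ = _select(list(curve.levels), curve.n, strategy, min_blocks)
    return sem


def ensemble_sem(
    ensemble: TrajectoryEnsemble,
    strategy: str = "max",
    mode: str = "pooled",
) -> float:
    """SEM of an ensemble's mean energy from reblocking.

    ``mode="pooled"`` (default) concatenates the trajectories in
    trajectory-id order and reblocks the pooled series: block boundaries
    that span independent trajectories can only lower the apparent
    correlation, which keeps the ``max``-rule estimate conservative.
    ``mode="per_trajectory"`` reblocks each trajectory separately and
    combines the K per-trajectory SEMs as sqrt(sum sem_t^2) / K, the SEM of
    an unweighted mean of independent trajectory means.
    """
    traces = sorted(ensemble.traces, key=lambda t: t.trajectory_id)
    if mode == "pooled":
        pooled = np.concatenate([t.values for t in traces])
        return reblock(pooled, strategy=strategy).selected_sem
    if mode == "per_trajectory":
        sems = [reblock(t.values, strategy=strategy).selected_sem for t in traces]
        return float(np.sqrt(np.sum(np.square(sems))) / len(sems))
    raise ValueError(f"unknown SEM mode {mode!r}")
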