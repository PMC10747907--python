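"""Adaptive block Metropolis-Hastings sampling on a bounded box.

The inference problem is posed in coordinates where every prior is a bounded
uniform (log10 coordinates for multiplicative scalings, natural coordinates
for additive log10 perturbations, log variance for the error term), so the
sampler operates on a box with flat prior contribution and a user-supplied
log-posterior.  Proposals are per-block Gaussian steps reflected at the box
bounds (a symmetric kernel, hence plain Metropolis acceptance).  Proposal
scales are adapted per block toward a target acceptance rate with a
Robbins-Monro recursion during burn-in only and frozen afterwards, which
preserves ergodicity of the post-burn-in chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["Block", "MCMCConfig", "ChainResult", "run_block_mh", "split_rhat", "ess_bulk"]


@dataclass(frozen=True)
class Block:
    """A named group of coordinate indices updated jointly."""

    name: str
    indices: tuple[int, ...]


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 20_000
    burn_in: int | None = None  # default: n_iter // 2
    n_chains: int = 4
    target_accept: float = 0.3
    seed: int = 0
    init_scale_frac: float = 0.1  # initial proposal sd as fraction of box span
    max_init_retries: int = 100

    def resolved_burn_in(self) -> int:
        b = self.n_iter // 2 if self.burn_in is None else self.burn_in
        if not (0 <= b < self.n_iter):
            raise ValueError(f"burn_in must lie in [0, n_iter), got {b}")
        return b


@dataclass
class ChainResult:
    """Post-burn-in draws and sampler metadata."""

    samples: np.ndarray  # (n_chains, n_kept, dim)
    accept_rates: dict[str, np.ndarray]  # block -> per-chain rate (post burn-in)
    final_scales: dict[str, np.ndarray]  # block -> per-chain adapted scale factor
    seed: int
    adaptation_history: dict[str, list[np.ndarray]] = field(default_factory=dict)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the bounds."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y <= span, y, 2.0 * span - y)


def run_block_mh(
    log_post: Callable[[np.ndarray], float],
    lo: np.ndarray,
    hi: np.ndarray,
    blocks: Sequence[Block],
    config: MCMCConfig,
    init: np.ndarray | None = None,
    gibbs: dict[str, Callable[[np.ndarray, np.random.Generator], np.ndarray]] | None = None,
) -> ChainResult:
    """Sample from ``exp(log_post)`` restricted to the box [lo, hi].

    ``log_post`` must return -inf outside its support; identical seed/config
    yields bit-identical chains.  Blocks named in ``gibbs`` are updated by an
    exact conditional draw (the callable returns the block's new coordinates
    given the full current state) instead of a Metropolis step.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if lo.shape != hi.shape or np.any(hi <= lo):
        raise ValueError("invalid bounds: need lo < hi elementwise")
    dim = lo.size
    covered = sorted(i for b in blocks for i in b.indices)
    if covered != list(range(dim)):
        raise ValueError("blocks must partition the coordinate indices")
    burn = config.resolved_burn_in()
    n_kept = config.n_iter - burn
    span = hi - lo

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    samples = np.empty((config.n_chains, n_kept, dim))
    accept = {b.name: np.zeros(config.n_chains) for b in blocks}
    scales = {b.name: np.zeros(config.n_chains) for b in blocks}
    history: dict[str, list[np.ndarray]] = {b.name: [] for b in blocks}

    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if init is not None:
            x = np.asarray(init, dtype=float).copy()
            lp = log_post(x)
            if not np.isfinite(lp):
                raise ValueError("non-finite posterior at the supplied init point")
        else:
            for _ in range(config.max_init_retries):
                x = lo + span * rng.random(dim)
                lp = log_post(x)
                if np.isfinite(lp):
                    break
            else:
                raise RuntimeError(
                    "could not find a finite-posterior initial point within "
                    f"{config.max_init_retries} prior draws"
                )
        log_s = {b.name: np.log(config.init_scale_frac) for b in blocks}
        n_acc = {b.name: 0 for b in blocks}
        n_prop = {b.name: 0 for b in blocks}
        adapt_t = {b.name: 0 for b in blocks}
        trace_s = {b.name: [] for b in blocks}

        for it in range(config.n_iter):
            adapting = it < burn
            for b in blocks:
                idx = np.asarray(b.indices)
                if gibbs and b.name in gibbs:
                    x[idx] = gibbs[b.name](x, rng)
                    lp = log_post(x)
                    if not adapting:
                        n_prop[b.name] += 1
                        n_acc[b.name] += 1
                    continue
                prop = x.copy()
                step = rng.normal(size=idx.size) * np.exp(log_s[b.name]) * span[idx]
                prop[idx] = _reflect(prop[idx] + step, lo[idx], hi[idx])
                lp_prop = log_post(prop)
                acc = np.log(rng.random()) < lp_prop - lp
                if acc:
                    x, lp = prop, lp_prop
                if adapting:
                    adapt_t[b.name] += 1
                    gain = adapt_t[b.name] ** -0.6
                    log_s[b.name] += gain * (float(acc) - config.target_accept)
                    # keep proposals numerically sane: a step of a few box
                    # spans already behaves as an independence kernel
                    log_s[b.name] = min(max(log_s[b.name], math.log(1e-6)), math.log(2.0))
                    trace_s[b.name].append(np.exp(log_s[b.name]))
                else:
                    n_prop[b.name] += 1
                    n_acc[b.name] += int(acc)
            if not adapting:
                samples[c, it - burn] = x

        for b in blocks:
            accept[b.name][c] = (
                n_acc[b.name] / n_prop[b.name] if n_prop[b.name] else np.nan
            )
            scales[b.name][c] = np.exp(log_s[b.name])
            history[b.name].append(np.asarray(trace_s[b.name]))

    return ChainResult(
        samples=samples,
        accept_rates=accept,
        final_scales=scales,
        seed=config.seed,
        adaptation_history=history,
    )


# ---------------------------------------------------------------------------
# Convergence summaries (thin wrappers kept here so toy samplers can use them)
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Degenerate chains (zero
    within-chain variance) return 1 when all chains agree and inf otherwise.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    sub = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = sub.mean(axis=1)
    within = sub.var(axis=1, ddof=1).mean()
    between = half * means.var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    return float(np.sqrt(((half - 1) / half * within + between / half) / within))


def ess_bulk(chains: np.ndarray) -> float:
    """Bulk effective sample size for one parameter, shape (n_chains, n_draws)."""
    import arviz as az

    return float(np.asarray(az.ess(az.convert_to_dataset(chains[:, :, None]))["x"].values).item())
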