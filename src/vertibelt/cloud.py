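"""Normal cloud model: backward and forward generators.

A cloud model represents a qualitative concept (here: "the distribution
height of a vegetation belt") by three numerical features:

* ``Ex`` — expectation, the centre of the concept's numeric domain;
* ``En`` — entropy, the fuzziness / spread of the concept, estimated as
  sqrt(pi/2) times the mean absolute deviation about Ex;
* ``He`` — hyper-entropy, the second-order uncertainty (the dispersion of En
  itself), estimated as sqrt(S - En^2) where S is the sample variance with
  divisor n - 1.

The *backward* generator estimates (Ex, En, He) from a sample.  The *forward*
generator draws cloud droplets: for each droplet, En' ~ Normal(En, He), then
x ~ Normal(Ex, En'), with membership exp(-(x - Ex)^2 / (2 En'^2)).

Moment-based He estimation can go degenerate on platykurtic samples
(S < En^2); the radicand is then clamped to zero and the parameters flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SampleSizeError, ValidationError

MIN_POINTS = 3  # fewer sample points cannot support a cloud model


@dataclass(frozen=True)
class CloudParameters:
    """The three numerical features of one cloud model, plus provenance."""

    ex: float
    en: float
    he: float
    n: int
    degenerate: bool = False  # He radicand was negative and clamped to 0


def backward_cloud(samples, min_points: int = MIN_POINTS) -> CloudParameters:
    """Estimate (Ex, En, He) from a 1-D sample of elevations.

    Ex is the sample mean; En = sqrt(pi/2) * mean |x_i - Ex|; He =
    sqrt(S - En^2) with S the (n-1)-divisor sample variance, clamped to 0
    (and flagged) when the radicand is negative.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < min_points:
        raise SampleSizeError(
            f"{x.size} sample points; at least {min_points} required"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples contain non-finite values")
    ex = float(x.mean())
    s = float(x.var(ddof=1))
    en = float(np.sqrt(np.pi / 2.0) * np.abs(x - ex).mean())
    radicand = s - en**2
    if radicand < 0.0:
        return CloudParameters(ex=ex, en=en, he=0.0, n=x.size, degenerate=True)
    return CloudParameters(ex=ex, en=en, he=float(np.sqrt(radicand)), n=x.size)


def membership(x, ex: float, en_prime: float):
    """Membership degree exp(-(x - Ex)^2 / (2 En'^2)); requires En' > 0."""
    if np.any(np.asarray(en_prime) <= 0):
        raise ValidationError("en_prime must be positive")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - ex) ** 2) / (2.0 * np.asarray(en_prime, dtype=float) ** 2))
    return out if out.ndim else float(out)


def forward_cloud(
    params: CloudParameters, m: int, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw *m* cloud droplets from (Ex, En, He).

    Each droplet: En' ~ Normal(En, He) (redrawn while En' <= 0), then
    x ~ Normal(Ex, En'), membership by the Gaussian kernel.  With He = 0 all
    En' equal En exactly; with En = 0 (zero-spread concept) all droplets sit
    at Ex with membership 1.  Deterministic for a fixed seed.

    Returns a frame with columns ``x_m`` and ``membership``.
    """
    if m < 0:
        raise ValidationError("droplet count m must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if m == 0:
        return pd.DataFrame({"x_m": [], "membership": []})
    if params.en == 0.0:
        return pd.DataFrame({"x_m": np.full(m, params.ex), "membership": np.ones(m)})

    if params.he == 0.0:
        en_prime = np.full(m, params.en)
    else:
        en_prime = rng.normal(params.en, params.he, size=m)
        bad = en_prime <= 0
        while bad.any():  # rejection-resample non-positive entropy draws
            en_prime[bad] = rng.normal(params.en, params.he, size=int(bad.sum()))
            bad = en_prime <= 0
    x = rng.normal(params.ex, en_prime)
    return pd.DataFrame({"x_m": x, "membership": membership(x, params.ex, en_prime)})


def fit_strata(
    points: pd.DataFrame,
    group_keys: list[str],
    value_col: str = "elevation_m",
    min_points: int = MIN_POINTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Backward-cloud parameters per stratum of *group_keys*.

    Returns ``(params, skipped)``: one row per stratum with n >= *min_points*
    (columns: the keys, n, Ex_m, En_m, He_m, degenerate), and a skip report
    for smaller strata (columns: the keys, n).  Row order is by sorted keys,
    so permuting the input leaves the output unchanged.
    """
    for key in group_keys:
        if key not in points.columns:
            raise ValidationError(f"grouping key {key!r} missing from points")
    fitted, skipped = [], []
    for keys, sub in points.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        record = dict(zip(group_keys, keys))
        if len(sub) < min_points:
            skipped.append({**record, "n": len(sub)})
            continue
        p = backward_cloud(sub[value_col].to_numpy(), min_points)
        fitted.append(
            {
                **record,
                "n": p.n,
                "Ex_m": p.ex,
                "En_m": p.en,
                "He_m": p.he,
                "degenerate": p.degenerate,
            }
        )
    params = pd.DataFrame(fitted, columns=[*group_keys, "n", "Ex_m", "En_m", "He_m", "degenerate"])
    skips = pd.DataFrame(skipped, columns=[*group_keys, "n"])
    return params, skips
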