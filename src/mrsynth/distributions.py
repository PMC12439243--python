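"""Declarative parameter sampling and distribution fitting.

Two directions: sample ModelParams draws from a declarative scheme
(uniform / normal / truncated-normal / constant per parameter), and,
inversely, identify the probability distribution that best describes a
column of spectral-fit parameters exported from an in-vivo fitting run.
Fits are scipy.stats maximum-likelihood estimates ranked by the
sum-of-squared-errors between the fitted density and a fixed-binning
histogram, with AIC as tiebreak.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .model import ModelParams

__all__ = [
    "ParamSpec",
    "DistFitResult",
    "DEFAULT_CANDIDATES",
    "sample_values",
    "sample_params",
    "fit_distributions",
    "load_fit_table",
]

log = logging.getLogger(__name__)

DEFAULT_CANDIDATES: tuple[str, ...] = ("norm", "truncnorm", "uniform", "gamma", "lognorm")

_HIST_BINS = 50


@dataclass(frozen=True)
class ParamSpec:
    """One parameter's sampling rule.

    ``dist``: "constant" (needs ``value``), "uniform" (``low``/``high``),
    "normal" (``mean``/``std``), or "truncnorm" (``mean``/``std`` plus
    ``low``/``high`` truncation bounds).
    """

    dist: str
    value: float = 0.0
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.0
    std: float = 1.0

    def __post_init__(self) -> None:
        if self.dist not in ("constant", "uniform", "normal", "truncnorm"):
            raise ValueError(f"unknown distribution family {self.dist!r}")
        if self.dist in ("uniform", "truncnorm") and self.high <= self.low:
            raise ValueError(f"{self.dist} spec requires low < high")
        if self.dist in ("normal", "truncnorm") and self.std < 0:
            raise ValueError("std must be non-negative")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "constant":
            return np.full(n, self.value)
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, n)
        if self.dist == "normal":
            return rng.normal(self.mean, self.std, n)
        a = (self.low - self.mean) / self.std
        b = (self.high - self.mean) / self.std
        return scipy.stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.std, size=n, random_state=rng
        )


def _as_spec(spec: ParamSpec | dict) -> ParamSpec:
    return spec if isinstance(spec, ParamSpec) else ParamSpec(**spec)


def sample_values(
    scheme: dict[str, ParamSpec | dict],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> dict[str, np.ndarray]:
    """Draw n values for every entry of a scheme; deterministic given seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return {key: _as_spec(spec).draw(n, rng) for key, spec in sorted(scheme.items())}


def sample_params(
    scheme: dict[str, ParamSpec | dict],
    n: int,
    basis_names: Sequence[str],
    rng: np.random.Generator | int | None = None,
) -> list[ModelParams]:
    """Draw n ModelParams from a declarative scheme.

    Scheme keys address ModelParams fields: scalar fields by name
    (``"phi0"``, ``"gauss_metab"``, ``"snr"`` ...) and per-name dictionaries
    with a dotted key (``"amplitude.NAA"``, ``"lorentz.Cr"``,
    ``"freq_shift.NAA"``).  Basis names without an explicit amplitude or
    lorentz entry default to constant 1.0 and 0.0 respectively.
    """
    draws = sample_values(scheme, n, rng)
    scalar_fields = {
        "gauss_metab",
        "gauss_mm",
        "freq_shift_global",
        "freq_shift_nuisance",
        "phi0",
        "phi1",
        "eddy_amp",
        "eddy_tc",
        "snr",
    }
    out = []
    for i in range(n):
        amplitude = {name: 1.0 for name in basis_names}
        lorentz = {name: 0.0 for name in basis_names}
        freq_shift: dict[str, float] = {}
        scalars: dict[str, float] = {}
        for key, values in draws.items():
            v = float(values[i])
            if "." in key:
                prefix, name = key.split(".", 1)
                if name not in basis_names:
                    raise ValueError(f"scheme entry {key!r} names an unknown basis function")
                if prefix == "amplitude":
                    amplitude[name] = v
                elif prefix == "lorentz":
                    lorentz[name] = v
                elif prefix == "freq_shift":
                    freq_shift[name] = v
                else:
                    raise ValueError(f"unknown per-name scheme prefix {prefix!r}")
            elif key in scalar_fields:
                scalars[key] = v
            else:
                raise ValueError(f"unknown scheme entry {key!r}")
        out.append(
            ModelParams(amplitude=amplitude, lorentz=lorentz, freq_shift=freq_shift, **scalars)
        )
    return out


@dataclass
class DistFitResult:
    """Per-family fits with goodness-of-fit scores and a ranking."""

    fits: dict[str, dict] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)

    @property
    def best(self) -> str:
        return self.ranking[0]

    @property
    def best_params(self) -> tuple:
        return self.fits[self.best]["params"]


def fit_distributions(
    samples: np.ndarray,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> DistFitResult:
    """Maximum-likelihood fit of each candidate family, ranked by fit quality.

    The score is the sum of squared errors between the fitted density and a
    50-bin density histogram of the samples; AIC breaks ties.  Families
    whose MLE fails on the data (e.g. support mismatch) are retained with an
    infinite score and the failure message.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError(f"need at least 30 samples to fit distributions, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("samples are constant; distribution fitting is degenerate")
    hist, edges = np.histogram(x, bins=_HIST_BINS, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fits: dict[str, dict] = {}
    for family in candidates:
        dist = getattr(scipy.stats, family, None)
        if dist is None or not hasattr(dist, "fit"):
            raise ValueError(f"unknown distribution family {family!r}")
        try:
            with np.errstate(all="ignore"):
                params = dist.fit(x)
                pdf = dist.pdf(centers, *params)
                sse = float(np.sum((hist - pdf) ** 2))
                loglik = float(np.sum(dist.logpdf(x, *params)))
            aic = 2 * len(params) - 2 * loglik
            if not np.isfinite(sse):
                raise FloatingPointError("non-finite fit score")
            fits[family] = {"params": tuple(params), "sse": sse, "aic": float(aic)}
        except Exception as exc:  # MLE failure on incompatible support
            fits[family] = {"params": None, "sse": np.inf, "aic": np.inf, "error": str(exc)}
    ranking = sorted(fits, key=lambda f: (fits[f]["sse"], fits[f]["aic"]))
    for rank, family in enumerate(ranking):
        fits[family]["rank"] = rank
    return DistFitResult(fits=fits, ranking=ranking)


def load_fit_table(
    path: str | Path,
    column_map: Optional[dict[str, str]] = None,
) -> dict[str, np.ndarray]:
    """Load a delimited table of fit parameters into named numeric columns.

    The delimiter is sniffed automatically; non-numeric columns are ignored;
    missing values are dropped per column with a logged count.
    ``column_map`` renames columns (e.g. an external export schema) before
    extraction.
    """
    path = Path(path)
    if not path.read_text().strip():
        raise ValueError(f"fit table {path} is empty")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"fit table {path} is empty") from exc
    except csv.Error:
        df = pd.read_csv(path)  # sniffer fails on single-column tables
    if df.empty:
        raise ValueError(f"fit table {path} contains no rows")
    if column_map:
        df = df.rename(columns=column_map)
    out: dict[str, np.ndarray] = {}
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        dropped = int(series.isna().sum())
        if dropped == len(series):
            log.info("column %r is non-numeric; skipped", col)
            continue
        if dropped:
            log.info("column %r: dropped %d missing values", col, dropped)
        out[col] = series.dropna().to_numpy()
    return out
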