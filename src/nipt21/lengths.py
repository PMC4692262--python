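"""cfDNA fragment-length models for fetal and maternal molecules.

Placenta-derived (fetal) cfDNA runs shorter than maternal cfDNA: the
landmark modes are ~143 bp versus ~166 bp (one nucleosome with and without
a linker).  The default model is a discretized log-normal for each origin,
parameterized by its mode and standard deviation on a 50-400 bp support.
An optional retention curve emulates bead-based physical size selection,
which enriches fragments around 155-160 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

SUPPORT_MIN = 50
SUPPORT_MAX = 400

FETAL_MODE_DEFAULT = 143
MATERNAL_MODE_DEFAULT = 166
LENGTH_SD_DEFAULT = 20.0


def _lognormal_params(mode: float, sd: float) -> tuple[float, float]:
    """Solve (mu, sigma) of a log-normal with the given mode and sd.

    mode = exp(mu - sigma^2); var = (exp(sigma^2)-1) * mode^2 * exp(3 sigma^2).
    """
    target = (sd / mode) ** 2

    def f(v: float) -> float:  # v = sigma^2
        return (np.exp(v) - 1.0) * np.exp(3.0 * v) - target

    v = brentq(f, 1e-10, 2.0)
    sigma = float(np.sqrt(v))
    mu = float(np.log(mode) + v)
    return mu, sigma


def discretized_lognormal_pmf(mode: float, sd: float) -> np.ndarray:
    """PMF over integer lengths 50..400 of a log-normal with given mode/sd."""
    from scipy.stats import lognorm

    mu, sigma = _lognormal_params(mode, sd)
    edges = np.arange(SUPPORT_MIN - 0.5, SUPPORT_MAX + 1.0, 1.0)
    cdf = lognorm.cdf(edges, s=sigma, scale=np.exp(mu))
    pmf = np.diff(cdf)
    pmf /= pmf.sum()
    return pmf


@dataclass(frozen=True)
class FragmentLengthModel:
    """Discrete fetal and maternal fragment-length distributions (50-400 bp)."""

    fetal_pmf: np.ndarray
    maternal_pmf: np.ndarray

    def __post_init__(self):
        n = SUPPORT_MAX - SUPPORT_MIN + 1
        for name in ("fetal_pmf", "maternal_pmf"):
            p = getattr(self, name)
            if p.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must be a probability vector")

    @property
    def support(self) -> np.ndarray:
        return np.arange(SUPPORT_MIN, SUPPORT_MAX + 1)

    def pmf(self, origin: str) -> np.ndarray:
        if origin == "fetal":
            return self.fetal_pmf
        if origin == "maternal":
            return self.maternal_pmf
        raise ValueError(f"origin must be 'fetal' or 'maternal', got {origin!r}")

    def mode(self, origin: str) -> int:
        return int(self.support[np.argmax(self.pmf(origin))])

    def mean(self, origin: str) -> float:
        return float(np.dot(self.support, self.pmf(origin)))

    def cdf_at(self, origin: str, length: int) -> float:
        """P(length <= given value) for the origin's distribution."""
        k = min(max(length, SUPPORT_MIN - 1), SUPPORT_MAX) - SUPPORT_MIN + 1
        return float(self.pmf(origin)[:k].sum()) if k > 0 else 0.0

    @classmethod
    def from_modes(
        cls,
        fetal_mode: float = FETAL_MODE_DEFAULT,
        maternal_mode: float = MATERNAL_MODE_DEFAULT,
        fetal_sd: float = LENGTH_SD_DEFAULT,
        maternal_sd: float = LENGTH_SD_DEFAULT,
    ) -> "FragmentLengthModel":
        if not fetal_mode < maternal_mode:
            raise ValueError("fetal mode must be below the maternal mode")
        return cls(
            fetal_pmf=discretized_lognormal_pmf(fetal_mode, fetal_sd),
            maternal_pmf=discretized_lognormal_pmf(maternal_mode, maternal_sd),
        )

    @classmethod
    def point_masses(cls, fetal: int, maternal: int) -> "FragmentLengthModel":
        """Degenerate model putting all mass on one length per origin."""
        n = SUPPORT_MAX - SUPPORT_MIN + 1
        f = np.zeros(n)
        m = np.zeros(n)
        f[fetal - SUPPORT_MIN] = 1.0
        m[maternal - SUPPORT_MIN] = 1.0
        return cls(fetal_pmf=f, maternal_pmf=m)


def sample_fragment_length(
    origin: str, model: FragmentLengthModel, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw ``n`` fragment lengths for the given origin (inverse-CDF)."""
    cdf = np.cumsum(model.pmf(origin))
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    return (SUPPORT_MIN + np.minimum(idx, SUPPORT_MAX - SUPPORT_MIN)).astype(np.int32)


def physical_selection_curve(
    lengths: np.ndarray,
    low_edge: float = 142.0,
    high_edge: float = 166.0,
    steepness: float = 4.0,
) -> np.ndarray:
    """Retention probability of a bead-based size selection.

    Double-sided logistic: rises through ``low_edge``, falls through
    ``high_edge``; with the defaults the retained fetal+maternal mixture
    peaks near 155-160 bp and short fetal fragments are enriched.
    """
    return expit((lengths - low_edge) / steepness) * expit(
        (high_edge - lengths) / steepness
    )


def apply_physical_selection(
    model: FragmentLengthModel,
    low_edge: float = 142.0,
    high_edge: float = 166.0,
    steepness: float = 4.0,
) -> tuple[FragmentLengthModel, float, float]:
    """Length model after physical size selection.

    Returns the reweighted model plus the per-origin retention masses
    (probability that a fetal / maternal molecule survives selection);
    the caller uses those to tilt the fetal fraction, since short fetal
    fragments survive preferentially.
    """
    r = physical_selection_curve(
        model.support.astype(float), low_edge, high_edge, steepness
    )
    fw = model.fetal_pmf * r
    mw = model.maternal_pmf * r
    f_mass = float(fw.sum())
    m_mass = float(mw.sum())
    if f_mass <= 0 or m_mass <= 0:
        raise ValueError("size-selection curve removes an origin entirely")
    return (
        FragmentLengthModel(fetal_pmf=fw / f_mass, maternal_pmf=mw / m_mass),
        f_mass,
        m_mass,
    )
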