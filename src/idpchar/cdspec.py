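"""Circular-dichroism quantification for disordered protein domains.

Covers conversion of raw differential absorbance to mean residue ellipticity
(MRE), helix-fraction estimation from the 220-nm MRE, the double-wavelength
(200/222 nm) random-coil vs premolten-globule classification, two-state
osmolyte-titration fitting (midpoint and m-value), isodichroic-point
detection, thermal-scan reversibility, and a constrained basis unmixing of
spectra into secondary-structure classes.

Model conventions
-----------------
The two-state titration model treats the helix fraction f at additive
concentration c as

    f(c) = f_min + (f_max - f_min) * K / (1 + K),
    K    = exp(-dG(c) / RT),   dG(c) = m * (Cm - c),

so the midpoint Cm and the m-value are direct fit parameters and
dG0 = m * Cm.  The fit runs on the concentration axis supplied (typically
% v/v); ``m_value`` is per axis unit and a strict %->molar conversion for
TFE is exposed separately (see docs/methods.md for why the conventional
literature value corresponds to the axis units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from . import constants as C

__all__ = [
    "CDSpectrum", "to_mre", "from_mre", "helix_fraction", "helix_mre_reference",
    "classify_double_wavelength", "DOUBLE_WAVELENGTH_BOXES",
    "TitrationFit", "TwoStateTitration", "fit_two_state_titration",
    "two_state_model", "detect_isodichroic", "ThermalScan",
    "thermal_reversibility", "BasisDeconvolver", "deconvolve_basis",
    "default_basis",
]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDSpectrum:
    """A far-UV CD trace with the metadata needed for MRE conversion.

    ``units`` is ``"delta_a"`` for raw differential absorbance or ``"mre"``
    for mean residue ellipticity (deg cm^2 dmol^-1).
    """

    wavelengths: np.ndarray
    signal: np.ndarray
    units: str = "delta_a"
    pathlength_cm: float | None = None
    conc_mg_ml: float | None = None
    n_residues: int | None = None
    mm_da: float | None = None
    temperature_c: float | None = None
    additive: tuple[str, float, str] | None = None  # (name, amount, unit)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "signal", sig)
        if wl.ndim != 1 or wl.size != sig.size:
            raise ValueError("wavelengths and signal must be 1-D and equal length")
        d = np.diff(wl)
        if wl.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength grid must be strictly monotone")
        if self.units not in ("delta_a", "mre"):
            raise ValueError("units must be 'delta_a' or 'mre'")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated signal at one wavelength."""
        wl, sig = self.wavelengths, self.signal
        if wl[0] > wl[-1]:
            wl, sig = wl[::-1], sig[::-1]
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(f"wavelength {wavelength} outside the measured range")
        return float(np.interp(wavelength, wl, sig))


def _check_meta(s: CDSpectrum) -> None:
    for name in ("pathlength_cm", "conc_mg_ml", "n_residues", "mm_da"):
        v = getattr(s, name)
        if v is None or v <= 0:
            raise ValueError(f"MRE conversion needs positive {name}")


def to_mre(spectrum: CDSpectrum) -> CDSpectrum:
    """Convert raw differential absorbance to MRE:
    theta = 3300 * M * dA / (l * c * n)."""
    if spectrum.units == "mre":
        raise ValueError("spectrum is already in MRE units")
    _check_meta(spectrum)
    factor = C.MRE_FACTOR * spectrum.mm_da / (
        spectrum.pathlength_cm * spectrum.conc_mg_ml * spectrum.n_residues
    )
    return replace(spectrum, signal=spectrum.signal * factor, units="mre")


def from_mre(spectrum: CDSpectrum) -> CDSpectrum:
    """Inverse of :func:`to_mre` (documented bijection)."""
    if spectrum.units == "delta_a":
        raise ValueError("spectrum is already raw")
    _check_meta(spectrum)
    factor = C.MRE_FACTOR * spectrum.mm_da / (
        spectrum.pathlength_cm * spectrum.conc_mg_ml * spectrum.n_residues
    )
    return replace(spectrum, signal=spectrum.signal / factor, units="delta_a")


def helix_mre_reference(n: int) -> float:
    """220-nm MRE expected for a 100% helical chain of n residues:
    -39500 * (1 - 2.57/n)."""
    if n < 3:
        raise ValueError("helix reference needs n >= 3")
    return C.HELIX_MRE_INF * (1.0 - C.HELIX_MRE_LENGTH_CORR / n)


def helix_fraction(mre220: float, n: int) -> tuple[float, bool]:
    """Helix fraction from the 220-nm MRE; returns ``(fraction, clipped)``.

    The raw ratio mre220 / reference is clipped to [0, 1]; ``clipped`` flags
    when clipping occurred.
    """
    f = mre220 / helix_mre_reference(n)
    clipped = not (0.0 <= f <= 1.0)
    return float(np.clip(f, 0.0, 1.0)), clipped


# ---------------------------------------------------------------------------
# double-wavelength classification
# ---------------------------------------------------------------------------

#: Rectangular reference regions on the ([theta]200, [theta]222) plane for
#: random-coil-like and premolten-globule-like disordered states, as
#: mean +/- 2 SD of the reference protein sets of the double-wavelength
#: plot (RC: theta200 -18900 +/- 2800, theta222 -1700 +/- 700;
#: PMG: theta200 -10700 +/- 1300, theta222 -3900 +/- 1100).  Configurable.
DOUBLE_WAVELENGTH_BOXES: dict[str, dict[str, tuple[float, float]]] = {
    "RC-like": {"mre200": (-24500.0, -13300.0), "mre222": (-3100.0, -300.0)},
    "PMG-like": {"mre200": (-13300.0, -8100.0), "mre222": (-6100.0, -1700.0)},
}


def classify_double_wavelength(
    mre200: float,
    mre222: float,
    boxes: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> str:
    """Classify a spectrum as RC-like, PMG-like or folded/other from its
    200-nm and 222-nm MRE values (rectangular region membership)."""
    boxes = DOUBLE_WAVELENGTH_BOXES if boxes is None else boxes
    for label, box in boxes.items():
        lo200, hi200 = box["mre200"]
        lo222, hi222 = box["mre222"]
        if lo200 <= mre200 <= hi200 and lo222 <= mre222 <= hi222:
            return label
    return "folded/other"


# ---------------------------------------------------------------------------
# two-state titration fit
# ---------------------------------------------------------------------------

def two_state_model(c, cm, m, f_min, f_max, rt):
    """Helix fraction of the two-state folding model (vectorized in c)."""
    c = np.asarray(c, dtype=float)
    k = np.exp(-m * (cm - c) / rt)
    return f_min + (f_max - f_min) * k / (1.0 + k)


@dataclass(frozen=True)
class TitrationFit:
    """Result of a two-state titration fit.

    ``m_value`` is per unit of the concentration axis supplied;
    ``m_value_molar`` applies the strict TFE %v/v -> molar conversion
    (division by 0.1393 M per %), flagged because the conventional
    literature values correspond to the axis units.
    """

    cm: float
    m_value: float
    f_min: float
    f_max: float
    temperature_k: float
    dg0: float
    r2: float
    residual_sd: float
    covariance: np.ndarray | None
    extrapolated: bool
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def m_value_molar(self) -> float:
        """m per mol/L assuming the axis was TFE % v/v (physical conversion)."""
        return self.m_value / C.TFE_MOLAR_PER_PERCENT

    def predict(self, c):
        rt = C.R_KCAL * self.temperature_k
        return two_state_model(c, self.cm, self.m_value, self.f_min, self.f_max, rt)


class TwoStateTitration:
    """sklearn-style estimator for the two-state osmolyte titration.

    Parameters
    ----------
    temperature_k : float
        Absolute temperature of the titration (default 293.15 K, i.e. the
        20 C of a standard CD experiment).
    bias_correction : {"none", "bootstrap"}
        Optional parametric-bootstrap bias correction of the fitted
        parameters; the sparse designs typical of CD titrations (5-11
        points, four free parameters) give the plain least-squares
        steepness a small upward bias.
    n_boot : int
        Bootstrap replicates when ``bias_correction="bootstrap"``.
    sigma : float or None
        Known measurement noise (helix-fraction units) used by the
        bootstrap; when None it is estimated from the fit residuals.
    random_state : int or numpy Generator, optional
        Seeds the bootstrap resampling.

    Attributes (after fit)
    ----------------------
    cm_, m_value_, f_min_, f_max_, dg0_, r2_ : float
    result_ : TitrationFit
    """

    _BOUNDS_M = (1e-6, 1.0)

    def __init__(self, temperature_k: float = 293.15, bias_correction: str = "none",
                 n_boot: int = 80, sigma: float | None = None, random_state=None):
        self.temperature_k = temperature_k
        self.bias_correction = bias_correction
        self.n_boot = n_boot
        self.sigma = sigma
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "temperature_k": self.temperature_k,
            "bias_correction": self.bias_correction,
            "n_boot": self.n_boot,
            "sigma": self.sigma,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "TwoStateTitration":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------

    def _fit_once(self, c: np.ndarray, f: np.ndarray, p0=None):
        rt = C.R_KCAL * self.temperature_k

        def model(cc, cm, m, fmin, fmax):
            return two_state_model(cc, cm, m, fmin, fmax, rt)

        span = c.max() - c.min()
        lo = [c.min() - span, self._BOUNDS_M[0], 0.0, 0.0]
        hi = [c.max() + span, self._BOUNDS_M[1], 1.0, 1.0]
        if p0 is not None:
            starts = [p0]
        else:
            order = np.argsort(c)
            f_lo, f_hi = float(f.min()), float(f.max())
            cm0 = float(np.clip(
                np.interp(0.5 * (f_lo + f_hi), f[order], c[order]),
                c.min() + 0.02 * span, c.max() - 0.02 * span,
            ))
            fmin0 = float(np.clip(f_lo, 0.0, 1.0))
            fmax0 = float(np.clip(f_hi, 0.0, 1.0))
            starts = [[cm0, m0, fmin0, fmax0] for m0 in (0.02, 0.05, 0.12)]
        best = None
        last_err: Exception | None = None
        for start in starts:
            try:
                popt, pcov = curve_fit(
                    model, c, f, p0=start, bounds=(lo, hi), maxfev=20000
                )
            except (RuntimeError, ValueError) as err:  # non-convergence
                last_err = err
                continue
            rss = float(np.sum((model(c, *popt) - f) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            raise RuntimeError(f"two-state fit did not converge: {last_err}")
        return best

    def fit(self, c, f) -> "TwoStateTitration":
        c = np.asarray(c, dtype=float)
        f = np.asarray(f, dtype=float)
        if c.size != f.size or c.size < 5:
            raise ValueError("need >= 5 (concentration, fraction) points")
        popt, pcov, rss = self._fit_once(c, f)
        notes: list[str] = []

        if self.bias_correction == "bootstrap":
            rng = np.random.default_rng(self.random_state)
            dof = max(c.size - 4, 1)
            sig = self.sigma if self.sigma is not None else float(np.sqrt(rss / dof))
            rt = C.R_KCAL * self.temperature_k
            clean = two_state_model(c, *popt, rt)
            boots = []
            for _ in range(self.n_boot):
                fb = clean + rng.normal(0.0, sig, c.size)
                try:
                    pb, _, _ = self._fit_once(c, fb, p0=popt)
                except RuntimeError:
                    continue
                boots.append(pb)
            if len(boots) >= max(10, self.n_boot // 2):
                bias = np.mean(boots, axis=0) - popt
                span = c.max() - c.min()
                lo = [c.min() - span, self._BOUNDS_M[0], 0.0, 0.0]
                hi = [c.max() + span, self._BOUNDS_M[1], 1.0, 1.0]
                popt = np.clip(popt - bias, lo, hi)
                notes.append(f"bootstrap bias correction ({len(boots)} replicates)")
            else:
                notes.append("bootstrap bias correction skipped: too few converged replicates")
        elif self.bias_correction != "none":
            raise ValueError("bias_correction must be 'none' or 'bootstrap'")

        cm, m, fmin, fmax = (float(v) for v in popt)
        rt = C.R_KCAL * self.temperature_k
        fitted = two_state_model(c, cm, m, fmin, fmax, rt)
        rss = float(np.sum((fitted - f) ** 2))
        ss_tot = float(np.sum((f - f.mean()) ** 2))
        extrapolated = not (c.min() <= cm <= c.max())
        if extrapolated:
            notes.append("transition midpoint outside the sampled range")
        if fmin >= fmax:
            notes.append("inverted baselines (f_min >= f_max)")
        self.result_ = TitrationFit(
            cm=cm, m_value=m, f_min=fmin, f_max=fmax,
            temperature_k=self.temperature_k, dg0=m * cm,
            r2=1.0 - rss / ss_tot if ss_tot > 0 else 1.0,
            residual_sd=float(np.sqrt(rss / max(c.size - 4, 1))),
            covariance=pcov, extrapolated=extrapolated, notes=tuple(notes),
        )
        self.cm_, self.m_value_ = cm, m
        self.f_min_, self.f_max_ = fmin, fmax
        self.dg0_, self.r2_ = self.result_.dg0, self.result_.r2
        return self

    def predict(self, c):
        return self.result_.predict(c)


def fit_two_state_titration(
    points: Sequence[tuple[float, float]] | np.ndarray,
    temperature_k: float = 293.15,
    **kwargs,
) -> TitrationFit:
    """Fit (concentration, helix-fraction) points to the two-state model."""
    arr = np.asarray(points, dtype=float)
    est = TwoStateTitration(temperature_k=temperature_k, **kwargs)
    est.fit(arr[:, 0], arr[:, 1])
    return est.result_


# ---------------------------------------------------------------------------
# isodichroic point
# ---------------------------------------------------------------------------

def detect_isodichroic(
    spectra: Sequence[CDSpectrum],
    spread_tolerance: float = 0.05,
    grid_step: float = 0.1,
) -> tuple[float, float] | None:
    """Find the wavelength where a family of spectra intersects.

    Spectra are interpolated onto a common fine grid over their shared
    wavelength range; the isodichroic point is the wavelength minimizing the
    across-spectra spread (max - min).  The detection is accepted when the
    minimal spread is below ``spread_tolerance`` times the family's dynamic
    range; returns ``(wavelength_nm, spread)`` or ``None`` (degenerate
    family, or no sufficiently tight crossing).
    """
    if len(spectra) < 3:
        raise ValueError("isodichroic detection needs >= 3 spectra")
    lo = max(min(s.wavelengths.min(), s.wavelengths.max()) for s in spectra)
    lo = max(float(s.wavelengths.min()) for s in spectra)
    hi = min(float(s.wavelengths.max()) for s in spectra)
    if hi <= lo:
        raise ValueError("spectra share no wavelength range")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mat = np.empty((len(spectra), grid.size))
    for i, s in enumerate(spectra):
        wl, sig = s.wavelengths, s.signal
        if wl[0] > wl[-1]:
            wl, sig = wl[::-1], sig[::-1]
        mat[i] = np.interp(grid, wl, sig)
    spread = mat.max(axis=0) - mat.min(axis=0)
    dynamic = float(mat.max() - mat.min())
    if dynamic == 0:
        return None  # identical flat spectra: no unique crossing
    tol = spread_tolerance * dynamic
    below = spread < tol
    if not below.any():
        return None
    if below.all():
        return None  # spectra indistinguishable everywhere: no unique point
    idx = int(np.argmin(spread))
    return float(grid[idx]), float(spread[idx])


# ---------------------------------------------------------------------------
# thermal scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalScan:
    """Fixed-wavelength (230 nm) ellipticity traces over a temperature ramp,
    heating plus optional cooling."""

    temperatures: np.ndarray
    heating: np.ndarray
    cooling: np.ndarray | None = None
    cooling_temperatures: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        h = np.asarray(self.heating, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "heating", h)
        if t.size != h.size or t.size < 3:
            raise ValueError("heating trace needs >= 3 points matching the grid")
        if self.cooling is not None:
            c = np.asarray(self.cooling, dtype=float)
            ct = self.cooling_temperatures
            ct = t if ct is None else np.asarray(ct, dtype=float)
            if ct.size != c.size:
                raise ValueError("cooling trace and its grid differ in length")
            object.__setattr__(self, "cooling", c)
            object.__setattr__(self, "cooling_temperatures", ct)


#: Hysteresis score below which heating and cooling are called reversible.
REVERSIBILITY_THRESHOLD = 0.05


def thermal_reversibility(
    scan: ThermalScan, threshold: float = REVERSIBILITY_THRESHOLD
) -> tuple[float, float | None, bool | None]:
    """Slope of the heating trace and hysteresis against the cooling trace.

    Returns ``(slope, hysteresis, reversible)``; the last two are ``None``
    when no cooling trace is present.  Hysteresis is the mean absolute
    heating-cooling difference (after interpolating the cooling trace onto
    the heating grid) divided by the heating-trace signal range.
    """
    t, h = scan.temperatures, scan.heating
    slope = float(linregress(t, h).slope)
    if scan.cooling is None:
        return slope, None, None
    ct, c = scan.cooling_temperatures, scan.cooling
    lo, hi = max(t.min(), ct.min()), min(t.max(), ct.max())
    if hi <= lo:
        raise ValueError("heating and cooling traces share no temperature range")
    mask = (t >= lo) & (t <= hi)
    order = np.argsort(ct)
    c_on_t = np.interp(t[mask], ct[order], c[order])
    rng = float(h.max() - h.min())
    if rng == 0:
        hysteresis = 0.0 if np.allclose(h[mask], c_on_t) else np.inf
    else:
        hysteresis = float(np.mean(np.abs(h[mask] - c_on_t)) / rng)
    return slope, hysteresis, hysteresis < threshold


# ---------------------------------------------------------------------------
# basis unmixing
# ---------------------------------------------------------------------------

def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def default_basis(wavelengths) -> dict[str, np.ndarray]:
    """Analytic Gaussian-mixture class shapes for helix, strand, turn and
    unordered structure (synthetic stand-ins for empirical CD basis sets;
    amplitudes in MRE units)."""
    wl = np.asarray(wavelengths, dtype=float)
    return {
        "helix": (
            _gauss(wl, 65000, 191, 4.5)
            + _gauss(wl, -35000, 208, 5.5)
            + _gauss(wl, -36000, 222, 6.0)
        ),
        "strand": _gauss(wl, 35000, 196, 4.5) + _gauss(wl, -15000, 218, 6.5),
        "turn": _gauss(wl, 8000, 205, 8.0) + _gauss(wl, -4000, 225, 7.0),
        "unordered": _gauss(wl, -42000, 198, 5.5) + _gauss(wl, 3000, 222, 8.0),
    }


class BasisDeconvolver:
    """Constrained unmixing of a CD spectrum into basis-class fractions.

    Non-negative least squares with the fractions constrained to sum to 1
    (enforced through a heavily weighted augmentation row, then an exact
    renormalization).  sklearn-style: ``fit`` stores the basis matrix,
    ``transform`` returns fractions for one or more spectra.
    """

    def __init__(self, condition_limit: float = 1e8, sum_weight: float = 1e6):
        self.condition_limit = condition_limit
        self.sum_weight = sum_weight

    def get_params(self, deep: bool = True) -> dict:
        return {"condition_limit": self.condition_limit, "sum_weight": self.sum_weight}

    def set_params(self, **params) -> "BasisDeconvolver":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, basis: Mapping[str, np.ndarray]) -> "BasisDeconvolver":
        if len(basis) < 2:
            raise ValueError("need at least 2 basis classes")
        self.classes_ = list(basis)
        mat = np.column_stack([np.asarray(basis[k], dtype=float) for k in self.classes_])
        scale = np.abs(mat).max()
        cond = float(np.linalg.cond(mat / scale))
        if cond > self.condition_limit:
            raise ValueError(f"ill-conditioned basis (condition number {cond:.3g})")
        self.basis_matrix_ = mat
        self.condition_ = cond
        return self

    def transform(self, signal: np.ndarray) -> tuple[dict[str, float], float]:
        """Return ``(fractions, residual_rms)`` for one spectrum signal
        sampled on the basis wavelength grid."""
        from scipy.optimize import nnls

        y = np.asarray(signal, dtype=float)
        mat = self.basis_matrix_
        if y.size != mat.shape[0]:
            raise ValueError("signal length does not match the basis grid")
        scale = np.abs(mat).max()
        a = np.vstack([mat / scale, self.sum_weight * np.ones(mat.shape[1])])
        b = np.concatenate([y / scale, [self.sum_weight]])
        w, _ = nnls(a, b)
        total = w.sum()
        if total <= 0:
            raise RuntimeError("unmixing returned an all-zero solution")
        w = w / total
        resid = float(np.sqrt(np.mean((mat @ w - y) ** 2)))
        return dict(zip(self.classes_, w)), resid


def deconvolve_basis(
    spectrum: CDSpectrum, basis: Mapping[str, np.ndarray]
) -> tuple[dict[str, float], float]:
    """Functional wrapper: unmix ``spectrum.signal`` against ``basis``
    (basis arrays must be sampled on the spectrum's wavelength grid)."""
    dec = BasisDeconvolver().fit(basis)
    return dec.transform(spectrum.signal)
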