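"""Deterministic synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, so any
dataset can be regenerated byte-identically.  The generators emulate the
study conditions of a disordered-domain characterization: composition- and
patterning-constrained sequences, two-state helix-fraction titrations, CD
spectral families mixing two basis shapes through an isodichroic point, SEC
calibration standards on a log-linear column line, and first-order enzyme
inactivation time courses with protection factors.

Noise is Gaussian everywhere; scales are explicit parameters recorded in
the emitted :class:`SyntheticDatasetSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import constants as C
from .cdspec import CDSpectrum, two_state_model
from .hydro import SECStandard, rs_calibrant
from .seqmetrics import kappa as kappa_metric
from .sequences import ProteinSequence

__all__ = [
    "SyntheticDatasetSpec", "gen_sequence", "gen_titration", "gen_cd_family",
    "gen_sec_standards", "gen_protection",
]

#: Default first-order heat-inactivation rate (1/min) of the unprotected
#: enzyme, chosen so that 11% of the initial activity remains after 60 min
#: at 43 C (the canonical unprotected LDH end point).
DEFAULT_K_UNPROTECTED = -float(np.log(0.11)) / 60.0


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Provenance record embedded in every generated dataset."""

    kind: str
    parameters: dict
    noise: tuple[str, float]
    seed: int


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_NEUTRAL_POOL = "AGHQSTNP"  # disorder-typical uncharged residues


def gen_sequence(
    n: int,
    f_plus: float,
    f_minus: float,
    kappa_target: float | None = None,
    seed: int = 0,
    kappa_tol: float = 0.01,
    max_iter: int = 20000,
) -> ProteinSequence:
    """Random sequence with exact charge composition and optional kappa.

    ``f_plus * n`` and ``f_minus * n`` must be integral (to 1e-6); positive
    residues are drawn from K/R, negatives from D/E, neutrals from a
    disorder-typical pool.  With a ``kappa_target``, charged/uncharged
    positions are stochastically swapped (greedy anneal) until the kappa of
    the arrangement is within ``kappa_tol`` of the target or ``max_iter``
    proposals are exhausted; the closest arrangement found is returned, and
    a ``ValueError`` is raised if it misses the tolerance.
    """
    npos = f_plus * n
    nneg = f_minus * n
    if abs(npos - round(npos)) > 1e-6 or abs(nneg - round(nneg)) > 1e-6:
        raise ValueError("f_plus*n and f_minus*n must be integers")
    npos, nneg = int(round(npos)), int(round(nneg))
    if npos + nneg > n:
        raise ValueError("infeasible composition: more charges than residues")
    if kappa_target is not None and not (0.0 <= kappa_target <= 1.0):
        raise ValueError("kappa_target must be in [0, 1]")

    rng = _rng(seed)
    pos = rng.choice(list("KR"), npos)
    neg = rng.choice(list("DE"), nneg)
    neu = rng.choice(list(_NEUTRAL_POOL), n - npos - nneg)
    residues = np.concatenate([pos, neg, neu])

    if kappa_target is None:
        rng.shuffle(residues)
        return ProteinSequence(
            id=f"synthetic-n{n}-seed{seed}", residues="".join(residues), source="synthetic"
        )

    if kappa_target >= 1.0 - kappa_tol:
        # the segregated construction attains kappa = 1 by definition
        seq = "".join(np.concatenate([np.sort(pos), neu, np.sort(neg)]))
        return ProteinSequence(id=f"synthetic-n{n}-seed{seed}", residues=seq, source="synthetic")

    rng.shuffle(residues)

    def kap(arr) -> float:
        s = ProteinSequence(id="tmp", residues="".join(arr), source="synthetic")
        return kappa_metric(s)[0]

    current = residues.copy()
    best = current.copy()
    k_cur = kap(current)
    k_best = k_cur
    for _ in range(max_iter):
        if abs(k_best - kappa_target) < kappa_tol:
            break
        i, j = rng.integers(0, n, 2)
        if current[i] == current[j]:
            continue
        current[i], current[j] = current[j], current[i]
        k_new = kap(current)
        if abs(k_new - kappa_target) <= abs(k_cur - kappa_target):
            k_cur = k_new
            if abs(k_new - kappa_target) < abs(k_best - kappa_target):
                best, k_best = current.copy(), k_new
        else:
            current[i], current[j] = current[j], current[i]
    if abs(k_best - kappa_target) >= kappa_tol:
        raise ValueError(
            f"kappa target {kappa_target} unreachable; best achieved {k_best:.4f}"
        )
    return ProteinSequence(
        id=f"synthetic-n{n}-seed{seed}", residues="".join(best), source="synthetic"
    )


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def gen_titration(
    cm: float,
    m: float,
    f_min: float,
    f_max: float,
    grid: Sequence[float],
    sigma: float,
    replicates: int = 1,
    seed: int = 0,
    temperature_k: float = 293.15,
) -> tuple[np.ndarray, np.ndarray, SyntheticDatasetSpec]:
    """Noisy two-state titration curves.

    Returns ``(grid, curves, spec)`` where ``curves`` has shape
    ``(replicates, len(grid))``; helix fractions are truncated to [0, 1].
    Replicate k is reproducible in isolation from ``(seed, k)`` because each
    replicate draws from its own child generator.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 5:
        raise ValueError("titration grid needs >= 5 points")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rt = C.R_KCAL * temperature_k
    clean = two_state_model(grid, cm, m, f_min, f_max, rt)
    curves = np.empty((replicates, grid.size))
    for k in range(replicates):
        rng = _rng(int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2**31)))
        curves[k] = np.clip(clean + rng.normal(0.0, sigma, grid.size), 0.0, 1.0)
    spec = SyntheticDatasetSpec(
        kind="titration",
        parameters={"cm": cm, "m": m, "f_min": f_min, "f_max": f_max,
                    "grid": grid.tolist(), "replicates": replicates,
                    "temperature_k": temperature_k},
        noise=("gaussian", sigma),
        seed=seed,
    )
    return grid, curves, spec


# ---------------------------------------------------------------------------
# CD spectral families
# ---------------------------------------------------------------------------

def make_crossing_bases(
    wavelengths: Sequence[float],
    crossing_nm: float,
    coil_like: np.ndarray | None = None,
    helix_like: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two basis spectra adjusted to intersect exactly at ``crossing_nm``.

    By construction every convex mixture of the two bases passes through the
    common value at the crossing wavelength, so a mixture family has an
    isodichroic point there.
    """
    from .cdspec import default_basis

    wl = np.asarray(wavelengths, dtype=float)
    shapes = default_basis(wl)
    b1 = shapes["unordered"] if coil_like is None else np.asarray(coil_like, float)
    b2 = shapes["helix"] if helix_like is None else np.asarray(helix_like, float)
    at = lambda b: float(np.interp(crossing_nm, wl, b))
    b2 = b2 + (at(b1) - at(b2))
    return b1, b2


def gen_cd_family(
    bases: Sequence[np.ndarray],
    weights: Sequence[Sequence[float]],
    wavelengths: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[CDSpectrum], SyntheticDatasetSpec]:
    """Spectral family as weighted sums of basis spectra plus noise.

    ``weights`` is one weight vector per spectrum; each must sum to 1.
    ``noise`` is the Gaussian sigma in signal units.
    """
    wl = np.asarray(wavelengths, dtype=float)
    mats = [np.asarray(b, dtype=float) for b in bases]
    if len(mats) < 2:
        raise ValueError("need >= 2 basis spectra")
    for b in mats:
        if b.size != wl.size:
            raise ValueError("basis grids do not match the wavelength grid")
    rng = _rng(seed)
    spectra = []
    for w in weights:
        w = np.asarray(w, dtype=float)
        if w.size != len(mats) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("each weight vector must match the bases and sum to 1")
        sig = sum(wi * bi for wi, bi in zip(w, mats))
        if noise > 0:
            sig = sig + rng.normal(0.0, noise, wl.size)
        spectra.append(CDSpectrum(wavelengths=wl, signal=sig, units="mre"))
    spec = SyntheticDatasetSpec(
        kind="cd-family",
        parameters={"n_bases": len(mats), "weights": [list(map(float, w)) for w in weights]},
        noise=("gaussian", noise),
        seed=seed,
    )
    return spectra, spec


# ---------------------------------------------------------------------------
# SEC standards
# ---------------------------------------------------------------------------

def gen_sec_standards(
    slope: float,
    intercept: float,
    mm_list: Sequence[float],
    ve_noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[SECStandard], SyntheticDatasetSpec]:
    """Calibration standards on the line log10(Rs) = slope*Ve + intercept.

    Radii come from the globular-calibrant law; elution volumes from the
    inverse line plus Gaussian noise of scale ``ve_noise`` (mL).
    """
    if len(mm_list) < 3:
        raise ValueError("need >= 3 standard masses")
    rng = _rng(seed)
    standards = []
    for i, mm in enumerate(mm_list):
        rs = float(rs_calibrant(mm))
        ve = (np.log10(rs) - intercept) / slope
        if ve_noise > 0:
            ve += rng.normal(0.0, ve_noise)
        standards.append(SECStandard(name=f"std{i+1}", mm=float(mm), elution_volume=float(ve)))
    spec = SyntheticDatasetSpec(
        kind="sec-standards",
        parameters={"slope": slope, "intercept": intercept, "mm_list": list(map(float, mm_list))},
        noise=("gaussian", ve_noise),
        seed=seed,
    )
    return standards, spec


# ---------------------------------------------------------------------------
# protection assays
# ---------------------------------------------------------------------------

def gen_protection(
    protection_factors: Mapping[str, float],
    times: Sequence[float],
    k_unprotected: float = DEFAULT_K_UNPROTECTED,
    a0_rate: float = 0.5,
    sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], SyntheticDatasetSpec]:
    """First-order enzyme-inactivation time courses with protection.

    Activity decays as ``A(t) = A0 * exp(-k * t / factor)``; a protection
    factor of 1 is the unprotected control and larger factors slow the
    decay.  Returns per-condition arrays of shape ``(replicates,
    len(times))`` of absorbance-rate observations (dA340/min) with Gaussian
    noise proportional to A0.
    """
    if k_unprotected <= 0:
        raise ValueError("k_unprotected must be positive")
    if any(f < 1 for f in protection_factors.values()):
        raise ValueError("protection factors must be >= 1")
    t = np.asarray(times, dtype=float)
    rng = _rng(seed)
    out = {}
    for name, factor in protection_factors.items():
        clean = a0_rate * np.exp(-k_unprotected * t / factor)
        obs = clean[None, :] + rng.normal(0.0, sigma * a0_rate, (replicates, t.size))
        out[name] = np.clip(obs, 0.0, None)
    spec = SyntheticDatasetSpec(
        kind="protection",
        parameters={"k_unprotected": k_unprotected, "a0_rate": a0_rate,
                    "factors": dict(protection_factors), "times": t.tolist(),
                    "replicates": replicates},
        noise=("gaussian-relative", sigma),
        seed=seed,
    )
    return out, spec
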