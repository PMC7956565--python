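"""Sequence-derived metrics for intrinsically disordered protein domains.

Implements the standard charge-patterning descriptors (f+, f-, FCR, NCPR,
kappa with blob-level charge asymmetry), the Das-Pappu phase-diagram region,
Kyte-Doolittle hydropathy (GRAVY and the windowed charge-hydropathy plot),
isoelectric point by Henderson-Hasselbalch bisection, average molecular
mass, composition deviation against the Swiss-Prot background, and an
in-silico Glu-C digest.

Charge convention (pH 7): K and R are +1, D and E are -1, histidine and the
chain termini are uncharged.  Fractions are counts over the residue number N.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight

from . import constants as C
from .sequences import ProteinSequence, SequenceError


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given sequence (e.g. kappa
    of a chargeless sequence) instead of silently returning NaN."""


# ---------------------------------------------------------------------------
# charge metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargeMetrics:
    """Charge composition and patterning of one sequence.

    ``ncpr`` is signed (f+ - f-); the absolute-value convention is exposed
    as :attr:`ncpr_abs`.  ``kappa``/``delta``/``delta_max`` are ``None`` when
    the sequence carries no charged residue.
    """

    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    kappa: float | None = None
    delta: float | None = None
    delta_max: float | None = None
    pdr: int | None = None

    @property
    def ncpr_abs(self) -> float:
        return abs(self.ncpr)


def charge_fractions(seq: ProteinSequence) -> ChargeMetrics:
    """f+, f-, FCR and signed NCPR as exact count ratios."""
    n = seq.n
    pos = sum(r in C.POSITIVE_RESIDUES for r in seq.residues)
    neg = sum(r in C.NEGATIVE_RESIDUES for r in seq.residues)
    f_plus = Fraction(pos, n)
    f_minus = Fraction(neg, n)
    return ChargeMetrics(
        f_plus=float(f_plus),
        f_minus=float(f_minus),
        fcr=float(f_plus + f_minus),
        ncpr=float(f_plus - f_minus),
    )


def _blob_sigma(charges: np.ndarray) -> float:
    """Charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-) of one blob; 0 when
    the blob carries no charge."""
    fp = np.mean(charges > 0)
    fm = np.mean(charges < 0)
    tot = fp + fm
    if tot == 0:
        return 0.0
    return (fp - fm) ** 2 / tot


def _delta(charges: np.ndarray, g: int) -> float:
    """Mean squared deviation of sliding-blob sigma from whole-chain sigma."""
    n = charges.size
    sigma_seq = _blob_sigma(charges)
    sigmas = np.array([_blob_sigma(charges[i : i + g]) for i in range(n - g + 1)])
    return float(np.mean((sigmas - sigma_seq) ** 2))


def _segregated_charges(charges: np.ndarray) -> np.ndarray:
    """Maximally segregated permutation: positives, then neutrals, then
    negatives."""
    pos = np.count_nonzero(charges > 0)
    neg = np.count_nonzero(charges < 0)
    neu = charges.size - pos - neg
    return np.concatenate([np.ones(pos), np.zeros(neu), -np.ones(neg)])


def kappa(seq: ProteinSequence, blob_sizes: Sequence[int] = (5, 6)) -> tuple[float, float, float]:
    """Charge-patterning parameter kappa with its delta and delta_max.

    For each blob size g, delta is the mean squared deviation of the sliding
    g-blob charge asymmetry from the whole-sequence asymmetry; delta_max is
    the same quantity for the maximally segregated arrangement of the same
    composition (positives, neutrals, negatives — and its mirror, taking the
    larger value).  kappa is the mean over blob sizes of delta/delta_max.

    Raises :class:`UndefinedMetricError` for chargeless sequences or when
    delta_max is zero (e.g. a single charged residue in specific layouts).
    """
    charges = np.array([C.RESIDUE_CHARGE[r] for r in seq.residues])
    if not np.any(charges):
        raise UndefinedMetricError("kappa undefined: sequence has no charged residues")
    if min(blob_sizes) < 2 or seq.n < max(blob_sizes):
        raise UndefinedMetricError("kappa undefined: sequence shorter than blob size")

    seg = _segregated_charges(charges)
    ratios, deltas, delta_maxes = [], [], []
    for g in blob_sizes:
        d = _delta(charges, g)
        dmax = max(_delta(seg, g), _delta(seg[::-1], g))
        if dmax == 0:
            raise UndefinedMetricError(
                f"kappa undefined: delta_max is zero for blob size {g}"
            )
        ratios.append(d / dmax)
        deltas.append(d)
        delta_maxes.append(dmax)
    return float(np.mean(ratios)), float(np.mean(deltas)), float(np.mean(delta_maxes))


def phase_region(f_plus: float, f_minus: float) -> int:
    """Das-Pappu diagram-of-states region (1-5) from the charge fractions.

    Region 4/5: positive/negative polyelectrolytes (one fraction above 0.35
    while the other is at most 0.35); region 3: strong polyampholytes
    (FCR > 0.35 with both fractions above 0.35); region 2: the boundary
    regime 0.25 <= FCR <= 0.35 (closed interval); region 1: weak
    polyampholytes and polyelectrolytes, FCR < 0.25.
    """
    if not (0 <= f_plus <= 1 and 0 <= f_minus <= 1 and f_plus + f_minus <= 1):
        raise ValueError("charge fractions must be in [0,1] with f+ + f- <= 1")
    fcr = f_plus + f_minus
    if f_plus > 0.35 and f_minus <= 0.35:
        return 4
    if f_minus > 0.35 and f_plus <= 0.35:
        return 5
    if fcr > 0.35:
        return 3
    if fcr >= 0.25:
        return 2
    return 1


def charge_metrics(seq: ProteinSequence, blob_sizes: Sequence[int] = (5, 6)) -> ChargeMetrics:
    """Full :class:`ChargeMetrics` including kappa and the phase region."""
    base = charge_fractions(seq)
    try:
        k, d, dmax = kappa(seq, blob_sizes)
    except UndefinedMetricError:
        k = d = dmax = None
    return ChargeMetrics(
        f_plus=base.f_plus,
        f_minus=base.f_minus,
        fcr=base.fcr,
        ncpr=base.ncpr,
        kappa=k,
        delta=d,
        delta_max=dmax,
        pdr=phase_region(base.f_plus, base.f_minus),
    )


# ---------------------------------------------------------------------------
# hydropathy / pI / mass
# ---------------------------------------------------------------------------

def gravy(seq: ProteinSequence) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value."""
    return float(np.mean([C.KYTE_DOOLITTLE[r] for r in seq.residues]))


def net_charge_at_pH(seq: ProteinSequence, pH: float) -> float:
    """Henderson-Hasselbalch net charge including termini."""
    counts: dict[str, int] = {}
    for r in seq.residues:
        counts[r] = counts.get(r, 0) + 1
    charge = 0.0
    for group, pk in C.PKA_POSITIVE.items():
        mult = 1 if group == "Nterm" else counts.get(group, 0)
        charge += mult / (1.0 + 10.0 ** (pH - pk))
    for group, pk in C.PKA_NEGATIVE.items():
        mult = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= mult / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(seq: ProteinSequence, tol: float = 0.005) -> float:
    """pH at which the Henderson-Hasselbalch net charge vanishes.

    The net charge is strictly decreasing in pH, so bisection on [0, 14]
    converges unconditionally; ``tol`` is the pH half-interval at stop.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge_at_pH(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def average_mass(seq: ProteinSequence) -> float:
    """Average (isotope-weighted) molecular mass in Da, including one water."""
    return float(molecular_weight(seq.residues, seq_type="protein", monoisotopic=False))


# ---------------------------------------------------------------------------
# composition deviation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionDeviation:
    """Per-residue deviation (CPX - CSPX)/CSPX against a reference
    composition, plus the TOP-IDP-ordered profile used for plotting."""

    deviation: dict[str, float]
    reference: str

    @property
    def top_idp_profile(self) -> list[tuple[str, float]]:
        return [(aa, self.deviation[aa]) for aa in C.TOP_IDP_ORDER]


def composition_deviation(
    seq: ProteinSequence,
    ref: Mapping[str, float] | None = None,
    ref_id: str | None = None,
) -> CompositionDeviation:
    """Relative composition deviation against Swiss-Prot (or a custom table).

    A residue absent from the sequence deviates by exactly -1.
    """
    if ref is None:
        ref = C.SWISSPROT_FREQS
        ref_id = ref_id or C.SWISSPROT_FREQS_ID
    if set(ref) != set(C.CANONICAL_AA) or min(ref.values()) <= 0:
        raise ValueError("reference must cover all 20 residues with positive frequencies")
    n = seq.n
    dev = {}
    for aa in C.CANONICAL_AA:
        cpx = seq.residues.count(aa) / n
        dev[aa] = (cpx - ref[aa]) / ref[aa]
    return CompositionDeviation(deviation=dev, reference=ref_id or "custom")


# ---------------------------------------------------------------------------
# charge-hydropathy (CH / RH) plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CHClassification:
    mean_net_charge: float
    mean_scaled_hydropathy: float
    boundary_hydropathy: float
    classification: str  # "disordered-side" | "ordered-side"


def charge_hydropathy_classify(seq: ProteinSequence) -> CHClassification:
    """Charge-hydropathy plot coordinates and boundary classification.

    Mean scaled hydropathy is the average over 5-residue windows of the
    Kyte-Doolittle value rescaled to [0, 1]; mean net charge is the absolute
    mean per-residue charge.  The boundary line is
    ``<H> = (<R> + 1.151) / 2.785``; points below it (hydropathy smaller than
    the boundary) fall on the disordered side, with the boundary itself
    assigned to the ordered side.
    """
    w = C.CH_WINDOW
    if seq.n < w:
        raise SequenceError(f"sequence shorter than CH window ({w})")
    h = np.array([C.KYTE_DOOLITTLE[r] for r in seq.residues])
    scaled = (h - C.KD_SCALE_MIN) / C.KD_SCALE_SPAN
    windows = np.convolve(scaled, np.ones(w) / w, mode="valid")
    mean_h = float(np.mean(windows))
    charges = np.array([C.RESIDUE_CHARGE[r] for r in seq.residues])
    mean_r = float(abs(np.mean(charges)))
    boundary = (mean_r + C.CH_BOUNDARY_INTERCEPT) / C.CH_BOUNDARY_SLOPE
    side = "disordered-side" if mean_h < boundary else "ordered-side"
    return CHClassification(mean_r, mean_h, boundary, side)


# ---------------------------------------------------------------------------
# Glu-C digest
# ---------------------------------------------------------------------------

def gluc_digest(
    seq: ProteinSequence, max_missed: int = 0
) -> list[tuple[str, int, int, float]]:
    """Theoretical Glu-C digest (cleavage after every D and E).

    Returns ``(peptide, start, end, average_mass)`` tuples with 1-based
    inclusive coordinates, enumerating products with up to ``max_missed``
    missed cleavages, ordered by start position then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    res = seq.residues
    cut_after = [i for i, r in enumerate(res) if r in "DE" and i < len(res) - 1]
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i for i in cut_after] + [len(res) - 1]
    out = []
    for si, start in enumerate(starts):
        for miss in range(max_missed + 1):
            ei = si + miss
            if ei >= len(ends):
                break
            end = ends[ei]
            pep = res[start : end + 1]
            mass = float(molecular_weight(pep, seq_type="protein", monoisotopic=False))
            out.append((pep, start + 1, end + 1, mass))
    return out


# ---------------------------------------------------------------------------
# per-sequence summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceSummary:
    id: str
    n: int
    avg_mass: float
    pI: float
    gravy: float
    charge: ChargeMetrics
    ch: CHClassification


def summarize(seq: ProteinSequence) -> SequenceSummary:
    """All scalar sequence metrics for one sequence (table row)."""
    return SequenceSummary(
        id=seq.id,
        n=seq.n,
        avg_mass=average_mass(seq),
        pI=isoelectric_point(seq),
        gravy=gravy(seq),
        charge=charge_metrics(seq),
        ch=charge_hydropathy_classify(seq),
    )


#: Fixed column order of the metrics report (mirrors the standard
#: characterization-table layout).
REPORT_COLUMNS = [
    "id", "N", "avg_mass", "pI", "f_plus", "f_minus", "FCR", "NCPR",
    "kappa", "GRAVY", "PDR",
]


def summary_row(s: SequenceSummary) -> dict:
    """One report row in :data:`REPORT_COLUMNS` order, rounded for display
    (3 decimals for fractions, integer Da, 2-decimal pI)."""
    return {
        "id": s.id,
        "N": s.n,
        "avg_mass": round(s.avg_mass),
        "pI": round(s.pI, 2),
        "f_plus": round(s.charge.f_plus, 3),
        "f_minus": round(s.charge.f_minus, 3),
        "FCR": round(s.charge.fcr, 3),
        "NCPR": round(s.charge.ncpr, 3),
        "kappa": None if s.charge.kappa is None else round(s.charge.kappa, 3),
        "GRAVY": round(s.gravy, 3),
        "PDR": s.charge.pdr,
    }
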