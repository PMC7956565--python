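"""Physical constants, residue scales and frozen reference tables.

Every numeric constant the analysis formulas use lives here so that the
provenance of any reported number can be audited from a single module.
"""

from __future__ import annotations

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Gas constant in kcal mol-1 K-1.
R_KCAL = 1.987204e-3

#: Average mass of one water molecule (Da), released per peptide bond.
WATER_AVG_MASS = 18.01528

# --- charge model (pH-7 convention) -------------------------------------
# K and R count +1, D and E count -1; histidine and the termini are treated
# as uncharged in all fraction-based metrics (f+, f-, FCR, NCPR, kappa).
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")

RESIDUE_CHARGE = {aa: 0.0 for aa in CANONICAL_AA}
RESIDUE_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})

# --- Kyte-Doolittle hydropathy scale -------------------------------------
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Linear rescale of the Kyte-Doolittle value to [0, 1]: (h + 4.5) / 9.
KD_SCALE_MIN = -4.5
KD_SCALE_SPAN = 9.0

#: Window length for the charge-hydropathy (CH) plot mean scaled hydropathy.
CH_WINDOW = 5

#: CH-plot boundary line: <H>_boundary = (<R> + 1.151) / 2.785, where <R> is
#: the absolute mean net charge per residue.  Sequences with mean scaled
#: hydropathy below the boundary fall on the disordered side.
CH_BOUNDARY_INTERCEPT = 1.151
CH_BOUNDARY_SLOPE = 2.785

# --- isoelectric point ----------------------------------------------------
# Bjellqvist pKa set as used by ProtParam-style calculators.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

# --- hydrodynamic power laws ----------------------------------------------
# log10(Rs/Angstrom) = slope * log10(MM/Da) + intercept
#: Globular SEC calibrant relation (natively folded globular proteins).
RS_CALIBRANT = (0.369, -0.254)
#: Natively folded relation of the Uversky compilation.
RS_NATIVELY_FOLDED = (0.357, -0.204)
#: Fully urea-unfolded relation.
RS_UNFOLDED = (0.521, -0.649)
#: IDP simple power law  Rs = R0 * N**nu  (Rs in Angstrom, N residues).
RS_IDP_R0 = 2.49
RS_IDP_NU = 0.509

# --- circular dichroism ---------------------------------------------------
#: MRE conversion factor:  theta = 3300 * M * dA / (l * c * n).
MRE_FACTOR = 3300.0
#: 100%-helix reference at 220 nm:  theta_220 = -39500 * (1 - 2.57/n).
HELIX_MRE_INF = -39500.0
HELIX_MRE_LENGTH_CORR = 2.57

#: TFE %v/v to molar conversion (density 1.393 g/mL, MW 100.04 g/mol):
#: 1% v/v = 0.1393 M.
TFE_MOLAR_PER_PERCENT = 0.1393

# --- SWISS-PROT average composition ---------------------------------------
# Frozen snapshot of the UniProtKB/Swiss-Prot average amino-acid frequencies
# (ExPASy ProtScale "A.A. composition" table, early-2021 release), as
# fractions.  Normalized to sum exactly to 1 on load.
SWISSPROT_FREQS_ID = "swissprot-protscale-2021"
_SWISSPROT_RAW = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.64, "T": 5.35, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}
_total = sum(_SWISSPROT_RAW.values())
SWISSPROT_FREQS = {aa: v / _total for aa, v in _SWISSPROT_RAW.items()}

#: Residues ordered by the TOP-IDP flexibility index, from the most
#: order-promoting (W) to the most disorder-promoting (P); used to lay out
#: composition-deviation profiles.
TOP_IDP_ORDER = list("WFYIMLVNCTAGRDHQKSEP")
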