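"""Published characterization values for the wheat and barley ABA-WDS
domains, used as inputs and regression references.

The observed quantities (masses, observed Stokes radii, titration
parameters) are experimental inputs to the analysis formulas; the derived
columns are the published table values the pipeline is expected to
reproduce from those inputs.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DomainReference:
    """One domain's published inputs and reference values."""

    id: str
    # mature 66-residue domain
    n_domain: int
    mm_domain: float      # Da, from sequence
    pI: float
    count_plus: int       # K+R
    count_minus: int      # D+E
    kappa: float
    gravy: float
    pdr: int
    # recombinant construct (vector-encoded N/C extensions included)
    n_recombinant: int
    mm_recombinant: float  # Da
    rs_obs: float          # Angstrom, from SEC
    ci: float              # published compaction index
    ratio_idp: float
    # TFE titration two-state fit
    tfe_midpoint: float    # % v/v
    tfe_m_value: float     # kcal/mol per axis unit


TT_ABA_WDS = DomainReference(
    id="TtABA-WDS",
    n_domain=66, mm_domain=7192.0, pI=6.12,
    count_plus=9, count_minus=13, kappa=0.096, gravy=-0.904, pdr=2,
    n_recombinant=83, mm_recombinant=9200.0, rs_obs=21.5,
    ci=0.46, ratio_idp=0.91,
    tfe_midpoint=27.0, tfe_m_value=0.049,
)

HV_ABA_WDS = DomainReference(
    id="HvABA-WDS",
    n_domain=66, mm_domain=7226.0, pI=6.24,
    count_plus=10, count_minus=13, kappa=0.087, gravy=-0.851, pdr=2,
    n_recombinant=83, mm_recombinant=9234.0, rs_obs=20.3,
    ci=0.59, ratio_idp=0.86,
    tfe_midpoint=27.0, tfe_m_value=0.042,
)

#: The four substitutions separating the two 66-residue domains
#: (1-based position, Tt residue, Hv residue).
TT_HV_SUBSTITUTIONS = [(10, "H", "R"), (17, "A", "V"), (45, "V", "L"), (63, "Q", "T")]

#: Vector-encoded extensions of the recombinant constructs.
RECOMBINANT_NTERM = "GSPEF"
RECOMBINANT_CTERM = "EFPGRLERPHRD"

#: Study conditions of the TFE titration experiment.
TFE_GRID_PERCENT = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0]
TITRATION_NOISE_SD = 0.01      # helix-fraction units
TITRATION_F_MIN = 0.05         # baseline helix fraction without TFE
TITRATION_F_MAX = 0.40         # fitted helical plateau
TITRATION_TEMPERATURE_K = 293.15
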