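"""Physical constants used across the relaxation and diffusion modules.

Values are CODATA; geometry/CSA defaults are the conventional solution-NMR
values for the backbone amide and methyl group.
"""

from scipy import constants as _sc

#: Vacuum permeability over 4π [T² m³ J⁻¹] — the dipolar prefactor μ0/4π.
MU0_OVER_4PI = _sc.mu_0 / (4.0 * _sc.pi)  # 1e-7

#: Reduced Planck constant [J s].
HBAR = _sc.hbar

#: ¹H gyromagnetic ratio [rad s⁻¹ T⁻¹].
GAMMA_H = 2.6752218744e8

#: ¹⁵N gyromagnetic ratio [rad s⁻¹ T⁻¹] (negative).
GAMMA_N = -2.7126e7

#: ¹H gyromagnetic ratio in gradient units [rad s⁻¹ G⁻¹].
GAMMA_H_PER_GAUSS = GAMMA_H * 1e-4

#: Backbone amide N–H bond length [m].
R_NH = 1.02e-10

#: ¹⁵N chemical shift anisotropy of the backbone amide [ppm].
CSA_N_PPM = -160.0

#: Angle between the ¹⁵N CSA principal axis and the N–H bond [degrees].
CSA_NH_ANGLE_DEG = 17.0

#: Distance between pairs of methyl protons [m].
R_HH_METHYL = 1.813e-10

#: Angle between the methyl symmetry axis and an H–H vector [degrees].
THETA_AXIS_HH_DEG = 90.0

#: Gas constant [kJ mol⁻¹ K⁻¹].
R_GAS_KJ = _sc.R / 1000.0


def p2(x: float) -> float:
    """Second Legendre polynomial P2(x) = (3x² − 1)/2."""
    return 0.5 * (3.0 * x * x - 1.0)
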