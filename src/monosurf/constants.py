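"""Physical constants and default material parameters (SI-derived units).

Internal unit conventions: coordinates in nm, molecular areas in Å²,
surface pressure / tension / compression modulus in mN·m⁻¹, surface
potential in V, dipole moments in Debye, pressures in bar.
"""

#: Avogadro constant, mol⁻¹ (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Vacuum permittivity, F·m⁻¹.
EPSILON_0 = 8.8541878128e-12

#: One Debye in C·m.
DEBYE = 3.33564e-30

#: Surface tension of the clean air–water interface, mN·m⁻¹ (298 K).
GAMMA_WATER = 72.0

#: bar·nm → mN·m⁻¹ (1 bar·nm = 1e5 Pa · 1e-9 m = 0.1 mN·m⁻¹).
BAR_NM_TO_MN_PER_M = 0.1

#: Å² → m².
A2_TO_M2 = 1.0e-20

#: Default molecular weights, g·mol⁻¹.  POPG as the sodium salt.
MW_DPPC = 734.04
MW_POPC = 760.08
MW_POPG_NA = 770.99
MW_CHOL = 386.65
MW_MOMETASONE_FUROATE = 521.40
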