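"""Published reference measurements of the Au / Au:Pt radio-enhancement study.

These are the wet-lab and simulated endpoint values of the cobalt-60
plasmid-irradiation study this package models. They serve as generating
truths for the synthetic-gel recovery analyses and as inputs to the
amplification-factor arithmetic; they are *measurements*, not quantities
this package recomputes from first principles.
"""

#: Fitted DSB damage yields m_DSB from the gel dose-response experiment,
#: in breaks·plasmid⁻¹·Gy⁻¹ (value, standard error). DMSO arms carry the
#: hydroxyl-radical scavenger.
GEL_DSB_YIELDS: dict[str, tuple[float, float]] = {
    "control": (17.47e-5, 0.51e-5),
    "au": (23.49e-5, 0.94e-5),
    "aupt": (33.18e-5, 0.54e-5),
    "control_dmso": (2.91e-5, 0.22e-5),
    "au_dmso": (3.56e-5, 0.13e-5),
    "aupt_dmso": (4.14e-5, 0.36e-5),
}

#: Track-structure-simulated DSB rates on the plasmid section, in
#: Gy⁻¹·Gbp⁻¹ (value, uncertainty). Absolute values are transport-code
#: outputs; only their ratios (amplification factors) are recomputed here.
SIMULATED_DSB_RATES: dict[str, tuple[float, float]] = {
    "control": (9.32, 0.05),
    "au": (13.10, 0.03),
    "aupt": (13.53, 0.02),
}

#: Experimental irradiation doses, Gy.
STUDY_DOSES: tuple[float, ...] = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0)

#: Metal concentration of the nanoparticle-loaded samples, mol/L.
METAL_CONCENTRATION_MOL_L = 4.23e-5

#: Nanoparticle count used in the simulated 50 µm³ water phantom.
PHANTOM_N_PARTICLES = 191
PHANTOM_VOLUME_UM3 = 50.0
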