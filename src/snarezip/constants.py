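"""Physical constants shared across the pipeline.

All forces are in pN, lengths in nm, energies in units of kBT unless a
suffix says otherwise.
"""

#: Thermal energy at the experimental temperature, pN nm.
KBT_PN_NM: float = 4.11

#: Diffusion-limited attempt frequency for protein folding transitions, s^-1.
#: Used to convert first-order rates into barrier heights (kBT units).
ATTEMPT_RATE_S: float = 1.0e6
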