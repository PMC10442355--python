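"""Shared class-code and channel conventions.

Ground-truth masks are single-channel rasters with integer codes; probability
maps carry one confidence channel per *detected* class. Benign glands are
annotated (code 3) so tests can exercise the benign-gland confounder, but they
are background as far as the nerve/tumor detectors are concerned.
"""

BACKGROUND = 0
TUMOR = 1
NERVE = 2
BENIGN_GLAND = 3

#: Valid ground-truth mask codes.
MASK_CODES = (BACKGROUND, TUMOR, NERVE, BENIGN_GLAND)

#: Probability-map channel order (fixed across the package).
CLASS_CHANNELS = {"tumor": 0, "nerve": 1}

#: Ground-truth mask code for each detected class.
CLASS_CODES = {"tumor": TUMOR, "nerve": NERVE}
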