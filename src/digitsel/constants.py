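"""Shared vocabulary: digit names, label codes, pairs."""

import math

#: digits studied, in somatotopic order along the central sulcus
DIGITS = ("D1", "D2", "D5")

#: integer codes used in winner-takes-all label maps (0 = unassigned)
LABEL_CODES = {"D1": 1, "D2": 2, "D5": 5}
CODE_TO_DIGIT = {v: k for k, v in LABEL_CODES.items()}

#: unordered digit pairs for overlap metrics
DIGIT_PAIRS = (("D1", "D2"), ("D1", "D5"), ("D2", "D5"))

#: sigma = FWHM_TO_SIGMA * fwhm for a Gaussian kernel
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
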