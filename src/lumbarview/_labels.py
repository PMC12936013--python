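"""Shared landmark-class / view-label mapping.

The intervertebral foramen (F) is the landmark seen in the paramedian
transverse foraminal view (PTFV); the transverse process (T) is the
landmark of the paramedian transverse view at the transverse-process level
(PTV-TP). The mapping is a bijection and every module imports it from
here — nothing redefines it locally.
"""

#: mask pixel value for each landmark class in 3-class label rasters
CLASS_VALUE = {"F": 1, "T": 2}
CLASS_FOR_VALUE = {v: k for k, v in CLASS_VALUE.items()}

VIEW_FOR_CLASS = {"F": "PTFV", "T": "PTV_TP"}
CLASS_FOR_VIEW = {v: k for k, v in VIEW_FOR_CLASS.items()}

VIEW_LABELS = ("PTV_TP", "PTFV")
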