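"""Per-patient feature schema.

The feature vector combines, for each of the spectral parametric maps,
mean intensity over the tumour core and margin, four Haralick texture
features of the core map, and two core-vs-margin image-quality metrics,
plus three molecular markers:

* 7 core means  (MBF, SS, SI, SAS, ASD, AAC, ACE)
* 6 margin means (no ACE: attenuation is estimated as a single core scalar)
* 24 core textures (6 maps x CON/COR/ENE/HOM; ACE has no map)
* 6 core-to-margin ratios (CMR)
* 6 core-to-margin contrast ratios (CMCR)

= 49 quantitative-ultrasound features; with ER/PR/HER2 receptor statuses
the model input is 52 features.
"""

from __future__ import annotations

MAP_PARAMS = ("MBF", "SS", "SI", "SAS", "ASD", "AAC")
ALL_PARAMS = MAP_PARAMS + ("ACE",)
TEXTURE_NAMES = ("CON", "COR", "ENE", "HOM")
MOLECULAR = ("ER", "PR", "HER2")

PARAM_UNITS = {
    "MBF": "dB",
    "SS": "dB/MHz",
    "SI": "dB",
    "SAS": "um",
    "ASD": "um",
    "AAC": "dB",
    "ACE": "dB/cm/MHz",
}


def qus_feature_names() -> list[str]:
    """The 49 quantitative-ultrasound feature names, in schema order."""
    names = [f"{p}_MEAN_CORE" for p in ALL_PARAMS]
    names += [f"{p}_MEAN_MARGIN" for p in MAP_PARAMS]
    for p in MAP_PARAMS:
        names += [f"{p}_{t}" for t in TEXTURE_NAMES]
    names += [f"{p}_CMR" for p in MAP_PARAMS]
    names += [f"{p}_CMCR" for p in MAP_PARAMS]
    return names


def full_feature_names() -> list[str]:
    """QUS features plus molecular receptor statuses (52 names)."""
    return qus_feature_names() + list(MOLECULAR)


def feature_dictionary() -> dict[str, str]:
    """Human-readable description of every feature name."""
    desc = {}
    for name in qus_feature_names():
        param = name.split("_")[0]
        unit = PARAM_UNITS[param]
        if name.endswith("_MEAN_CORE"):
            desc[name] = f"mean {param} over tumour-core map [{unit}]"
        elif name.endswith("_MEAN_MARGIN"):
            desc[name] = f"mean {param} over 5 mm margin map [{unit}]"
        elif name.endswith("_CMR"):
            desc[name] = f"core-to-margin mean ratio of {param} map"
        elif name.endswith("_CMCR"):
            desc[name] = f"core-to-margin contrast ratio of {param} map"
        else:
            tex = name.split("_")[1]
            desc[name] = f"GLCM {tex} of core {param} map (16 levels)"
    desc["ER"] = "estrogen receptor status (0/1)"
    desc["PR"] = "progesterone receptor status (0/1)"
    desc["HER2"] = "HER2 receptor status (0/1)"
    return desc
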