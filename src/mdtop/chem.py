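"""Frozen element data.

Van der Waals radii (Å) after Bondi (J. Phys. Chem. 68, 1964), the set most
structural tools default to.  Shipped as a literal so tunnel geometry is
bit-reproducible.
"""

VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
}

DEFAULT_VDW = 1.70  # fallback for unlisted elements


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
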