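"""Shared builders for synthetic cell specs used across the suite."""

from coccoloc import CellSpec


def make_punctate_spec(centre=(24.0, 24.0), radius=8.0, n_puncta=6, contrast=3.0,
                       angles=None, cytoplasm=0.2, **kw):
    return CellSpec(
        centre=centre, radius_px=radius, pattern="punctate", n_puncta=n_puncta,
        puncta_contrast=contrast, puncta_angles=angles, cytoplasm_level=cytoplasm, **kw,
    )


def make_ring_spec(centre=(24.0, 24.0), radius=8.0, cytoplasm=0.2, **kw):
    return CellSpec(centre=centre, radius_px=radius, pattern="homogeneous_ring",
                    cytoplasm_level=cytoplasm, **kw)
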