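"""Built-in 10–20 scalp montage for the 32-channel shooting-study cap.

Coordinates are unit-sphere (x: left→right, y: back→front, z: up), taken
from the standard extended 10–20 layout and symmetrized so that homologous
left/right sites are exact mirror images and midline sites have x = 0.
Labels not in this table require user-supplied positions.
"""

from __future__ import annotations

import numpy as np

# fmt: off
MONTAGE_32: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.3304, +0.9406, -0.0784),
    "Fpz": (+0.0000, +0.9998, -0.0194),
    "Fp2": (+0.3304, +0.9406, -0.0784),
    "F7":  (-0.8469, +0.5135, -0.1384),
    "F3":  (-0.6010, +0.6324, +0.4888),
    "Fz":  (+0.0000, +0.6608, +0.7506),
    "F4":  (+0.6010, +0.6324, +0.4888),
    "F8":  (+0.8469, +0.5135, -0.1384),
    "FC5": (-0.9293, +0.2287, +0.2900),
    "FC1": (-0.3807, +0.2900, +0.8780),
    "FC2": (+0.3807, +0.2900, +0.8780),
    "FC6": (+0.9293, +0.2287, +0.2900),
    "M1":  (-0.7254, -0.3798, -0.5741),
    "T7":  (-0.9777, -0.1793, -0.1088),
    "C3":  (-0.7140, -0.1215, +0.6896),
    "Cz":  (+0.0000, -0.0911, +0.9958),
    "C4":  (+0.7140, -0.1215, +0.6896),
    "T8":  (+0.9777, -0.1793, -0.1088),
    "M2":  (+0.7254, -0.3798, -0.5741),
    "CP5": (-0.8250, -0.4694, +0.3148),
    "CP1": (-0.3391, -0.4330, +0.8352),
    "CP2": (+0.3391, -0.4330, +0.8352),
    "CP6": (+0.8250, -0.4694, +0.3148),
    "P7":  (-0.7044, -0.7094, -0.0243),
    "P3":  (-0.4898, -0.7092, +0.5071),
    "Pz":  (+0.0000, -0.7006, +0.7136),
    "P4":  (+0.4898, -0.7092, +0.5071),
    "P8":  (+0.7044, -0.7094, -0.0243),
    "POz": (+0.0000, -0.8961, +0.4438),
    "O1":  (-0.2544, -0.9641, +0.0757),
    "Oz":  (+0.0000, -0.9920, +0.1265),
    "O2":  (+0.2544, -0.9641, +0.0757),
}
# fmt: on

DEFAULT_CHANNELS: list[str] = list(MONTAGE_32)

#: Homologous left/right pairs, used for mirror-symmetry operations.
LR_PAIRS: list[tuple[str, str]] = [
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("FC1", "FC2"), ("M1", "M2"), ("T7", "T8"), ("C3", "C4"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("O1", "O2"),
]

#: Frontopolar sites where ocular artifacts are largest.
FRONTAL_SITES = ("Fp1", "Fpz", "Fp2")


def is_valid_site(label: str) -> bool:
    return label in MONTAGE_32


def positions_for(labels: list[str],
                  extra: dict[str, tuple[float, float, float]] | None = None,
                  ) -> np.ndarray:
    """Unit-sphere positions (n_channels, 3) for ``labels``.

    Raises KeyError naming the first label with no built-in or
    user-supplied position.
    """
    table = dict(MONTAGE_32)
    if extra:
        table.update(extra)
    out = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        if lab not in table:
            raise KeyError(f"no scalp position known for electrode {lab!r}; "
                           "supply one explicitly")
        v = np.asarray(table[lab], dtype=float)
        out[i] = v / np.linalg.norm(v)
    return out


def frontal_weights(labels: list[str]) -> np.ndarray:
    """Per-channel weight of an ocular (frontopolar) source, in [0, 1].

    Weight decays with great-circle distance from Fpz, so blink-like
    deflections are strongest at Fp1/Fpz/Fp2 and small posteriorly.
    """
    pos = positions_for(labels)
    ref = np.asarray(MONTAGE_32["Fpz"])
    cosd = np.clip(pos @ ref, -1.0, 1.0)
    ang = np.arccos(cosd)  # radians from Fpz
    return np.exp(-((ang / 0.8) ** 2))
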