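"""Standard 64-channel scalp layout and sensor adjacency.

Positions are idealized unit-sphere coordinates derived from the extended
10-20 nomenclature: good enough for occipital channel selection, spatial
mixing in the simulator, and neighbourhood graphs for cluster statistics.
Coordinates are (x, y, z) with +x right, +y anterior, +z superior.
"""

from __future__ import annotations

import numpy as np

#: Default occipital channel set used for the virtual channel.
OCCIPITAL_LABELS = ("O1", "Oz", "O2", "PO3", "PO4", "PO7", "PO8", "POz")

# (label, anterior-posterior fraction nasion=0 .. inion=1, lateral fraction
# left=-1 .. right=+1 of the head circumference)
_LAYOUT_TABLE = [
    ("Fp1", 0.1, -0.35), ("Fpz", 0.1, 0.0), ("Fp2", 0.1, 0.35),
    ("AF7", 0.2, -0.8), ("AF3", 0.2, -0.4), ("AFz", 0.2, 0.0),
    ("AF4", 0.2, 0.4), ("AF8", 0.2, 0.8),
    ("F7", 0.3, -1.0), ("F5", 0.3, -0.75), ("F3", 0.3, -0.5),
    ("F1", 0.3, -0.25), ("Fz", 0.3, 0.0), ("F2", 0.3, 0.25),
    ("F4", 0.3, 0.5), ("F6", 0.3, 0.75), ("F8", 0.3, 1.0),
    ("FT7", 0.4, -1.0), ("FC5", 0.4, -0.75), ("FC3", 0.4, -0.5),
    ("FC1", 0.4, -0.25), ("FCz", 0.4, 0.0), ("FC2", 0.4, 0.25),
    ("FC4", 0.4, 0.5), ("FC6", 0.4, 0.75), ("FT8", 0.4, 1.0),
    ("T7", 0.5, -1.0), ("C5", 0.5, -0.75), ("C3", 0.5, -0.5),
    ("C1", 0.5, -0.25), ("Cz", 0.5, 0.0), ("C2", 0.5, 0.25),
    ("C4", 0.5, 0.5), ("C6", 0.5, 0.75), ("T8", 0.5, 1.0),
    ("TP7", 0.6, -1.0), ("CP5", 0.6, -0.75), ("CP3", 0.6, -0.5),
    ("CP1", 0.6, -0.25), ("CPz", 0.6, 0.0), ("CP2", 0.6, 0.25),
    ("CP4", 0.6, 0.5), ("CP6", 0.6, 0.75), ("TP8", 0.6, 1.0),
    ("P9", 0.7, -1.25), ("P7", 0.7, -1.0), ("P5", 0.7, -0.75),
    ("P3", 0.7, -0.5), ("P1", 0.7, -0.25), ("Pz", 0.7, 0.0),
    ("P2", 0.7, 0.25), ("P4", 0.7, 0.5), ("P6", 0.7, 0.75),
    ("P8", 0.7, 1.0), ("P10", 0.7, 1.25),
    ("PO7", 0.8, -0.8), ("PO3", 0.8, -0.4), ("POz", 0.8, 0.0),
    ("PO4", 0.8, 0.4), ("PO8", 0.8, 0.8),
    ("O1", 0.9, -0.35), ("Oz", 0.9, 0.0), ("O2", 0.9, 0.35),
    ("Iz", 1.0, 0.0),
]

# Labels that any reduced montage must keep so that the occipital virtual
# channel and the stimulation-montage anchors (CPz, Iz) stay available.
_REQUIRED = set(OCCIPITAL_LABELS) | {"Cz", "CPz", "Iz"}


def _to_xyz(f_ap: float, f_lat: float) -> tuple[float, float, float]:
    t = np.pi * f_ap
    alpha = f_lat * np.pi / 2.0
    return (float(np.sin(t) * np.sin(alpha)),
            float(np.cos(t)),
            float(np.sin(t) * np.cos(alpha)))


def standard_layout(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Return ``(labels, positions)`` for an ``n_channels``-channel montage.

    For ``n_channels < 64`` a subset is taken that always retains the
    occipital set plus Cz/CPz/Iz, filling the remainder with an even spread
    over the other sites.
    """
    if not 3 <= n_channels <= len(_LAYOUT_TABLE):
        raise ValueError(f"n_channels must be in [3, {len(_LAYOUT_TABLE)}]")
    all_labels = [row[0] for row in _LAYOUT_TABLE]
    if n_channels == len(_LAYOUT_TABLE):
        chosen = all_labels
    else:
        required = [lb for lb in all_labels if lb in _REQUIRED]
        if n_channels <= len(required):
            chosen = required[:n_channels]
        else:
            rest = [lb for lb in all_labels if lb not in _REQUIRED]
            n_fill = n_channels - len(required)
            idx = np.linspace(0, len(rest) - 1, n_fill).round().astype(int)
            fill = {rest[i] for i in np.unique(idx)}
            chosen = [lb for lb in all_labels if lb in _REQUIRED or lb in fill]
    coords = {row[0]: _to_xyz(row[1], row[2]) for row in _LAYOUT_TABLE}
    positions = np.array([coords[lb] for lb in chosen], dtype=float)
    return list(chosen), positions


def adjacency_matrix(positions: np.ndarray, radius_factor: float = 1.6) -> np.ndarray:
    """Boolean sensor-neighbourhood matrix from 3-D positions.

    Two sensors are neighbours when their Euclidean distance is below
    ``radius_factor`` times the median nearest-neighbour distance.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least two sensors")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = np.median(d.min(axis=1))
    adj = d < radius_factor * nn
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    return adj
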