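"""Per-crown-class tail SCP from a deposited thick-filament atomic model.

Given a helically reconstructed C-zone model (myosin heavy chains with their
full coiled-coil tails), this traces the coiled-coil midline of each tail
from the alpha-carbon couples of its two heavy chains and reports one SCP
per crown class.  Chain pairing and crown assignment can be supplied
explicitly; otherwise heavy chains are identified by length, paired by
mean-coordinate proximity of their tail regions, and assigned to crown
classes by the axial position of the motor domain modulo the crown spacing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AtomModel, select_atoms
from .sinuosity import coiled_coil_midline, sinuosity

__all__ = ["tail_scp_by_crown"]

# myosin heavy chain: motor domain ends near residue 780; the tail
# (S2 + LMM coiled coil) follows
DEFAULT_TAIL_START = 840
MIN_HEAVY_CHAIN_RESIDUES = 800


def _ca_points(model: AtomModel, chain: str, resi_range=None):
    return select_atoms(model, chains=[chain], residues=resi_range,
                        atom_names="CA")


def tail_scp_by_crown(
    model: AtomModel,
    pairs: Optional[Sequence[tuple[str, str, int]]] = None,
    tail_start: int = DEFAULT_TAIL_START,
    crown_spacing: float = 430.0 / 3.0,
) -> pd.DataFrame:
    """SCP of each myosin tail, grouped by crown class.

    Parameters
    ----------
    model : the thick-filament atomic model.
    pairs : optional explicit ``(chain_a, chain_b, crown_class)`` triples;
        when omitted, heavy chains are detected and paired automatically.
    tail_start : first residue of the coiled-coil tail.
    crown_spacing : axial spacing between successive crowns, used for the
        automatic crown-class assignment.

    Returns a frame with one row per tail (chains, crown class, C, L, SCP)
    plus the per-class mean SCP in the ``scp_class_mean`` column.
    """
    if pairs is None:
        pairs = _autodetect_pairs(model, tail_start, crown_spacing)
    rows = []
    for chain_a, chain_b, cls in pairs:
        a = _ca_points(model, chain_a, (tail_start, 10 ** 6))
        b = _ca_points(model, chain_b, (tail_start, 10 ** 6))
        mid = coiled_coil_midline(a, b)
        res = sinuosity(mid)
        rows.append({"chain_a": chain_a, "chain_b": chain_b,
                     "crown_class": cls, "C_A": res.C, "L_A": res.L,
                     "S": res.S, "SCP": res.SCP})
    frame = pd.DataFrame(rows)
    frame["scp_class_mean"] = frame.groupby("crown_class")["SCP"].transform("mean")
    return frame.sort_values(["crown_class", "chain_a"]).reset_index(drop=True)


def _autodetect_pairs(model: AtomModel, tail_start: int,
                      crown_spacing: float):
    counts = model.atoms[model.atoms["atom"] == "CA"].groupby("chain").size()
    heavy = [c for c, n in counts.items() if n >= MIN_HEAVY_CHAIN_RESIDUES]
    if len(heavy) < 2 or len(heavy) % 2:
        raise ValueError(
            f"cannot auto-pair heavy chains (found {len(heavy)}); "
            "pass explicit (chain_a, chain_b, crown_class) pairs")
    tails = {}
    heads_z = {}
    for c in heavy:
        ca = _ca_points(model, c, (tail_start, 10 ** 6))
        tails[c] = ca.coords.mean(axis=0)
        head = _ca_points(model, c, (1, tail_start - 1))
        heads_z[c] = float(head.coords[:, 2].mean()) if len(head) else 0.0
    # greedy mutual-nearest pairing of tail centroids
    remaining = set(heavy)
    pairs = []
    while remaining:
        c0 = min(remaining)
        remaining.discard(c0)
        partner = min(remaining,
                      key=lambda c: np.linalg.norm(tails[c] - tails[c0]))
        remaining.discard(partner)
        z = 0.5 * (heads_z[c0] + heads_z[partner])
        cls = int(round(z / crown_spacing)) % 3 + 1
        pairs.append((c0, partner, cls))
    return pairs
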