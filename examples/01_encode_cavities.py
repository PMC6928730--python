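"""Encode a cavity's spheres into a sentence of canonical node IDs.

Builds a tiny five-atom molecule and a three-sphere cavity record, picks
the four nearest atoms per sphere, and prints the resulting tokens.
"""

import numpy as np

from cavity2vec import CavityRecord, encode_sequence
from cavity2vec.structures import Atom

atoms = [
    Atom(serial=i, name="C1", element="C", res_name="ALA", res_seq=i,
         chain="A", position=pos, vdw_radius=1.7)
    for i, pos in enumerate([(0, 0, 0), (2, 0, 0), (0, 2, 0),
                             (0, 0, 2), (6, 6, 6)], start=1)
]

record = CavityRecord(
    cavity_id="demo", snapshot=0,
    centers=np.array([[0.5, 0.5, 0.5], [1.0, 1.0, 1.0], [4.0, 4.0, 4.0]]),
    radii=np.array([1.2, 0.9, 1.4]),
)

sequence = encode_sequence(record, atoms, mode="center")
print("tokens:", " ".join(sequence.tokens))
# Each token is the sorted serials of the sphere's four nearest atoms.
# The first two spheres sit near atoms 1-4, so they share one node ID;
# the last sphere is closer to atom 5, which displaces the farthest atom.
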