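"""The 20-letter amino-acid alphabet used throughout the package.

Residues are indexed in the standard PAML/phylip order
``ARNDCQEGHILKMFPSTWYV``; ``-`` is the gap character and is treated as
missing data everywhere.  Ambiguity codes (B, Z, X, ...) are rejected at
parse time.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
GAP: str = "-"
N_STATES: int = 20

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CODE: int = -1


def encode(sequence: str) -> np.ndarray:
    """Encode an aligned amino-acid string as int8 codes (gap -> -1).

    Raises
    ------
    ValueError
        If the sequence contains a symbol outside the 20-letter alphabet
        plus gap.
    """
    out = np.empty(len(sequence), dtype=np.int8)
    for j, ch in enumerate(sequence.upper()):
        if ch == GAP:
            out[j] = GAP_CODE
        else:
            code = AA_INDEX.get(ch)
            if code is None:
                raise ValueError(f"illegal symbol {ch!r} at column {j + 1}; "
                                 f"allowed: {AMINO_ACIDS} and {GAP!r}")
            out[j] = code
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(GAP if c == GAP_CODE else AMINO_ACIDS[c] for c in codes)
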