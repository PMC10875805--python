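"""Canonical amino-acid alphabet and 13-mer window geometry.

Every matrix in the package is indexed (offset, amino acid) with offsets
-6..+6 (phosphoacceptor at 0) down the rows and the 20 canonical
one-letter codes, in the fixed order below, across the columns.  The "J"
placeholder marks window positions that fall beyond a protein terminus;
it is never a matrix column.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = len(AMINO_ACIDS)

PAD: str = "J"
ACCEPTORS: frozenset[str] = frozenset("STY")

WINDOW: int = 13
HALF_WINDOW: int = 6
OFFSETS: tuple[int, ...] = tuple(range(-HALF_WINDOW, HALF_WINDOW + 1))
CENTER_ROW: int = HALF_WINDOW  # row index of offset 0


def offset_to_row(offset: int) -> int:
    """Map an offset in -6..+6 to its matrix row index 0..12."""
    if not -HALF_WINDOW <= offset <= HALF_WINDOW:
        raise ValueError(f"offset {offset} outside -{HALF_WINDOW}..+{HALF_WINDOW}")
    return offset + HALF_WINDOW


def row_to_offset(row: int) -> int:
    """Inverse of :func:`offset_to_row`."""
    if not 0 <= row < WINDOW:
        raise ValueError(f"row {row} outside 0..{WINDOW - 1}")
    return row - HALF_WINDOW
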