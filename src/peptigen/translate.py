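"""In silico translation helpers shared by the proteome builders.

Standard genetic code (table 1). Codons that are not in the standard
forward table — stops, codons containing ambiguous bases, and the
contextual selenocysteine codon — all translate to the stop symbol
``*``, which keeps downstream stop-splitting conservative.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

from .kmers import revcomp

STOP = "*"

_FORWARD = dict(standard_dna_table.forward_table)


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` from ``frame`` (0, 1 or 2) to the first out-of-range codon."""
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    nt = nt.upper()
    aa = []
    for i in range(frame, len(nt) - 2, 3):
        aa.append(_FORWARD.get(nt[i : i + 3], STOP))
    return "".join(aa)


def translate_orf(nt: str) -> str:
    """Translate frame 0, stopping at the first stop codon (exclusive)."""
    aa = translate(nt, 0)
    stop = aa.find(STOP)
    return aa if stop == -1 else aa[:stop]


def three_frame(nt: str) -> list[tuple[int, str]]:
    """Forward-strand translations: [(frame, aa), ...] for frames 0..2."""
    return [(f, translate(nt, f)) for f in (0, 1, 2)]


def six_frame(nt: str) -> list[tuple[str, int, str]]:
    """Both-strand translations: [(strand, frame, aa), ...]."""
    out = [("+", f, translate(nt, f)) for f in (0, 1, 2)]
    rc = revcomp(nt)
    out += [("-", f, translate(rc, f)) for f in (0, 1, 2)]
    return out


def split_at_stops(aa: str, min_len: int = 8, mode: str = "split_all") -> list[str]:
    """Cut a translation at stop codons and keep fragments of >= ``min_len`` aa.

    ``split_all`` keeps every inter-stop fragment (maximizes candidate
    space); ``prefix_only`` keeps only the fragment preceding the first
    stop.
    """
    if mode == "split_all":
        fragments = aa.split(STOP)
    elif mode == "prefix_only":
        fragments = [aa.split(STOP)[0]]
    else:
        raise ValueError(f"unknown stop-splitting mode: {mode!r}")
    return [f for f in fragments if len(f) >= min_len]
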