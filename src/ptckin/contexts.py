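"""mRNA sequence contexts around a premature termination codon (PTC).

Every kinetic and readthrough measurement in this package is indexed by a
six-codon window of the message: the codon immediately upstream of the stop
(codon 5, nt -1..-3), the stop codon itself (codon 6, nt +1..+3), and the
four downstream codons (codons 7-10, nt +4..+15).  The upstream codon is
either held constant at CAA (which favors readthrough) or taken from the
patient sequence; the downstream codons mostly reproduce patient sequences.

Chimeric contexts splice the proximal downstream codons (7-8) from one
context onto the distal downstream codons (9-10) of another, which is how
the relative influence of proximal versus distal downstream sequence on
release-factor activity is dissected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

STOP_CODONS = frozenset({"UGA", "UAA", "UAG"})
RNA_ALPHABET = frozenset("ACGU")

#: nt positions conventionally attached to each codon slot (codon 5 .. codon 10),
#: with +1 at the first stop-codon base and -1 immediately upstream.
NT_NUMBERING: dict[int, tuple[int, int, int]] = {
    5: (-3, -2, -1),
    6: (1, 2, 3),
    7: (4, 5, 6),
    8: (7, 8, 9),
    9: (10, 11, 12),
    10: (13, 14, 15),
}


class ContextError(ValueError):
    """Raised when a codon string cannot form a valid PTC context."""


def _normalize_codon(codon: str, position: int) -> str:
    """Uppercase, DNA->RNA transliterate, and validate a single triplet."""
    c = codon.strip().upper().replace("T", "U")
    if len(c) != 3 or not set(c) <= RNA_ALPHABET:
        raise ContextError(
            f"codon {position}: {codon!r} is not a triplet over A/C/G/U (or T)"
        )
    return c


@dataclass(frozen=True)
class SequenceContext:
    """Codons 5-10 of a pretermination mRNA context.

    Parameters
    ----------
    label : str
        Free-text identifier, e.g. ``"CF-R1162X"``.
    upstream_codon : str
        Codon 5 (nt -1..-3), the P-site codon.
    stop_codon : str
        Codon 6 (nt +1..+3); must be UGA, UAA or UAG.
    downstream_codons : tuple of str
        Codons 7-10 (nt +4..+15), exactly four sense triplets.
    upstream_mode : {"constant_CAA", "patient"}
        Whether codon 5 is the constant readthrough-permissive CAA or the
        patient-derived codon.
    """

    label: str
    upstream_codon: str
    stop_codon: str
    downstream_codons: tuple[str, ...]
    upstream_mode: str = field(default="constant_CAA")

    def __post_init__(self) -> None:
        up = _normalize_codon(self.upstream_codon, 5)
        stop = _normalize_codon(self.stop_codon, 6)
        if stop not in STOP_CODONS:
            raise ContextError(
                f"codon 6 must be a stop triplet (UGA/UAA/UAG); got {stop!r}"
            )
        if up in STOP_CODONS:
            raise ContextError(f"codon 5 must be a sense codon; got {up!r}")
        if len(self.downstream_codons) != 4:
            raise ContextError(
                f"expected 4 downstream codons, got {len(self.downstream_codons)}"
            )
        down = tuple(
            _normalize_codon(c, i) for i, c in enumerate(self.downstream_codons, 7)
        )
        internal_stops = [c for c in down if c in STOP_CODONS]
        if internal_stops:
            # unusual but not forbidden: the panel never uses internal stops
            warnings.warn(
                f"{self.label}: internal stop codon(s) {internal_stops} in codons 7-10",
                stacklevel=2,
            )
        mode = "constant_CAA" if up == "CAA" else "patient"
        if self.upstream_mode not in ("constant_CAA", "patient"):
            raise ContextError(f"invalid upstream_mode {self.upstream_mode!r}")
        object.__setattr__(self, "upstream_codon", up)
        object.__setattr__(self, "stop_codon", stop)
        object.__setattr__(self, "downstream_codons", down)
        object.__setattr__(self, "upstream_mode", mode)

    @property
    def codons(self) -> tuple[str, ...]:
        """Codons 5-10 in order."""
        return (self.upstream_codon, self.stop_codon) + self.downstream_codons

    def render(self) -> str:
        """Whitespace-joined codon string, inverse of :func:`parse_context`."""
        return " ".join(self.codons)

    def codon(self, position: int) -> str:
        """Codon by its slot number (5..10)."""
        if position not in NT_NUMBERING:
            raise ContextError(f"codon position must be 5..10, got {position}")
        return self.codons[position - 5]


def parse_context(codon_string: str, label: str = "") -> SequenceContext:
    """Parse a whitespace-separated 6-codon RNA (or DNA) string.

    The first triplet is codon 5, the second the stop codon, the remaining
    four codons 7-10.  T is transliterated to U.

    >>> parse_context("CAA UGA CUA AUG ACC UUU", "Reference").stop_codon
    'UGA'
    """
    tokens = codon_string.split()
    if len(tokens) != 6:
        raise ContextError(
            f"expected 6 whitespace-separated codons, got {len(tokens)}: {codon_string!r}"
        )
    return SequenceContext(
        label=label,
        upstream_codon=tokens[0],
        stop_codon=tokens[1],
        downstream_codons=tuple(tokens[2:]),
    )


def make_chimera(
    proximal_source: SequenceContext,
    distal_source: SequenceContext,
    label: str | None = None,
) -> SequenceContext:
    """Splice a chimeric context: codons 5-8 from one parent, 9-10 from the other.

    The upstream codon, stop codon and proximal downstream codons (7-8) come
    from ``proximal_source``; the distal downstream codons (9-10) come from
    ``distal_source``.
    """
    if label is None:
        label = f"{proximal_source.label}/{distal_source.label}"
    return SequenceContext(
        label=label,
        upstream_codon=proximal_source.upstream_codon,
        stop_codon=proximal_source.stop_codon,
        downstream_codons=proximal_source.downstream_codons[:2]
        + distal_source.downstream_codons[2:],
    )


def swap_upstream(ctx: SequenceContext, new_codon5: str) -> SequenceContext:
    """Replace codon 5, e.g. patient codon <-> the constant CAA."""
    c5 = _normalize_codon(new_codon5, 5)
    if c5 in STOP_CODONS:
        raise ContextError(f"codon 5 must be a sense codon; got {c5!r}")
    mode = "constant_CAA" if c5 == "CAA" else "patient"
    return replace(ctx, upstream_codon=c5, upstream_mode=mode)
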