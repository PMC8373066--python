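"""Sliding-bulge motifs, their degenerate states, and homopolymer run scanning.

A single extra base inserted inside a mononucleotide repeat tract forms a
bulge that is not pinned to one position: the bulged base can exchange with
any identical neighbor, so the defect slides laterally through the tract.
A tract offering N identical positions gives an N-fold degenerate ensemble.
The motif notation used throughout is lowercase flanks around an uppercase
bulged base, with an explicit repeat count for tracts longer than one, e.g.
``aTc`` (non-slide, N=1), ``cTTc`` or ``cT2c`` (two-slide), ``cT14c``
(14 degenerate positions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MOTIF_RE = re.compile(r"^([acgt])([ACGT]+)([0-9]*)([acgt])$")


class MotifError(ValueError):
    """Raised for malformed or physically impossible motif specifications."""


def _check_base(symbol: str, what: str = "base") -> str:
    if symbol not in BASES:
        raise MotifError(f"invalid {what} {symbol!r}: must be one of A, C, G, T")
    return symbol


@dataclass(frozen=True, order=True)
class BulgeState:
    """One degenerate conformation: a bulged base with its nearest neighbors.

    ``tTt`` with multiplicity m means the ensemble contains m equivalent
    positions whose bulged base and both nearest neighbors are T.  The
    interior ("triplet") state of a sliding bulge has nn5 == bulged == nn3.
    """

    nn5: str
    bulged: str
    nn3: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        for b in (self.nn5, self.bulged, self.nn3):
            _check_base(b)
        if self.multiplicity < 1:
            raise MotifError(f"multiplicity must be >= 1, got {self.multiplicity}")

    @property
    def key(self) -> str:
        """Canonical label, e.g. ``aTc`` or ``tTt``."""
        return f"{self.nn5.lower()}{self.bulged}{self.nn3.lower()}"

    @property
    def is_triplet(self) -> bool:
        return self.nn5 == self.bulged == self.nn3

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


@dataclass(frozen=True, order=True)
class BulgeMotif:
    """A sliding-bulge locus: flanks, bulged base, and tract length.

    ``n`` counts repeat bases on the bulged (longer) strand, which equals
    the number of degenerate bulge positions: n=1 is a non-slide bulge,
    n=2 a two-slide bulge, n>=3 an N-slide bulge.
    """

    flank5: str
    bulged: str
    flank3: str
    n: int = 1

    def __post_init__(self) -> None:
        _check_base(self.flank5, "5' flank")
        _check_base(self.bulged, "bulged base")
        _check_base(self.flank3, "3' flank")
        if self.flank5 == self.bulged:
            raise MotifError(
                f"5' flank equals the bulged base ({self.bulged}); the tract "
                "would extend through the flank"
            )
        if self.flank3 == self.bulged:
            raise MotifError(
                f"3' flank equals the bulged base ({self.bulged}); the tract "
                "would extend through the flank"
            )
        if self.n < 1:
            raise MotifError(f"repeat count must be >= 1, got {self.n}")

    def render(self, compact: bool = True) -> str:
        """Canonical string form; round-trips through :func:`parse_motif`.

        ``compact=False`` writes the tract out in full (``cTTTc`` style),
        which is only sensible for short tracts.
        """
        f5, f3 = self.flank5.lower(), self.flank3.lower()
        if self.n == 1:
            return f"{f5}{self.bulged}{f3}"
        if not compact and self.n <= 12:
            return f"{f5}{self.bulged * self.n}{f3}"
        return f"{f5}{self.bulged}{self.n}{f3}"

    @property
    def motif_class(self) -> str:
        if self.n == 1:
            return "non_slide"
        if self.n == 2:
            return "two_slide"
        return "sliding"

    @property
    def non_slide_key(self) -> str:
        """Table key of the corresponding non-slide bulge (n ignored)."""
        return f"{self.flank5.lower()}{self.bulged}{self.flank3.lower()}"

    @property
    def two_slide_key(self) -> str:
        """Table key of the corresponding two-slide bulge (flank.BB.flank)."""
        return f"{self.flank5.lower()}{self.bulged}{self.bulged}{self.flank3.lower()}"

    @property
    def triplet_key(self) -> str:
        """Table key of the interior triplet state, e.g. ``tTt``."""
        b = self.bulged
        return f"{b.lower()}{b}{b.lower()}"

    def __str__(self) -> str:
        return self.render()


def parse_motif(spec: str) -> BulgeMotif:
    """Parse a motif string such as ``aTc``, ``cTTc`` or ``cT14c``.

    The grammar is a lowercase 5' flank, the uppercase bulged base (written
    once with an optional integer count, or repeated literally), and a
    lowercase 3' flank.  The count defaults to 1.
    """
    if not isinstance(spec, str):
        raise MotifError(f"motif spec must be a string, got {type(spec).__name__}")
    m = _MOTIF_RE.match(spec)
    if m is None:
        raise MotifError(
            f"malformed motif {spec!r}: expected <flank><BULGED[count]><flank>, "
            "e.g. 'aTc', 'cTTc' or 'cT14c'"
        )
    flank5, tract, count, flank3 = m.groups()
    if len(set(tract)) != 1:
        raise MotifError(f"mixed bases in repeat tract of {spec!r}: {tract}")
    if count:
        if len(tract) > 1:
            raise MotifError(
                f"ambiguous motif {spec!r}: use either a repeated base or a count"
            )
        n = int(count)
        if n < 1:
            raise MotifError(f"repeat count must be >= 1 in {spec!r}")
    else:
        n = len(tract)
    return BulgeMotif(flank5.upper(), tract[0], flank3.upper(), n)


def reverse_complement(motif: BulgeMotif) -> BulgeMotif:
    """The same insertion viewed from the opposite strand.

    A bulged A inside an A-tract is a bulged T inside a T-tract on the
    reverse complement; the flanks swap and complement.  The model is
    strand-specific, so both views are distinct motifs.
    """
    return BulgeMotif(
        COMPLEMENT[motif.flank3],
        COMPLEMENT[motif.bulged],
        COMPLEMENT[motif.flank5],
        motif.n,
    )


def enumerate_states(motif: BulgeMotif) -> list[BulgeState]:
    """Degenerate conformations of a sliding bulge with multiplicities.

    The bulge at either end of the tract sees one flank and one repeat base
    (terminal states); every interior position sees repeat bases on both
    sides (the triplet state, multiplicity n-2).  Total multiplicity is n.
    """
    f5, b, f3 = motif.flank5, motif.bulged, motif.flank3
    if motif.n == 1:
        return [BulgeState(f5, b, f3)]
    states = [BulgeState(f5, b, b), BulgeState(b, b, f3)]
    if motif.n > 2:
        states.append(BulgeState(b, b, b, multiplicity=motif.n - 2))
    return states


def enumerate_motifs(
    motif_class: str, n_range: tuple[int, int] | None = None
) -> list[BulgeMotif]:
    """All distinct motifs of a class.

    ``non_slide`` and ``two_slide`` each have 4 x 3 x 3 = 36 members (four
    bulged bases, three choices per flank).  ``sliding`` takes an inclusive
    ``n_range`` with lower bound >= 2 and yields 36 motifs per length.
    """
    if motif_class == "non_slide":
        lengths: Iterable[int] = (1,)
    elif motif_class == "two_slide":
        lengths = (2,)
    elif motif_class == "sliding":
        if n_range is None:
            raise MotifError("sliding enumeration requires an n_range")
        lo, hi = n_range
        if lo < 2:
            raise MotifError(f"sliding motifs need n >= 2, got range [{lo}, {hi}]")
        if hi < lo:
            raise MotifError(f"empty n_range [{lo}, {hi}]")
        lengths = range(lo, hi + 1)
    else:
        raise MotifError(
            f"unknown motif class {motif_class!r}: "
            "expected non_slide, two_slide or sliding"
        )
    out = []
    for n in lengths:
        for b in BASES:
            for f5 in BASES:
                if f5 == b:
                    continue
                for f3 in BASES:
                    if f3 == b:
                        continue
                    out.append(BulgeMotif(f5, b, f3, n))
    return out


def required_building_blocks(motifs: Iterable[BulgeMotif]) -> set[str]:
    """Parameter keys a table set must carry to score the given motifs.

    Sliding bulges of any length decompose into the 36 two-slide composites
    plus the 4 interior triplet states, so over all sliding motifs the union
    has exactly 40 members.
    """
    keys: set[str] = set()
    for m in motifs:
        if m.n == 1:
            keys.add(m.non_slide_key)
        else:
            keys.add(m.two_slide_key)
            if m.n >= 3:
                keys.add(m.triplet_key)
    return keys


@dataclass(frozen=True)
class MicrosatelliteRun:
    """A maximal homopolymer run in a sequence (0-based, half-open)."""

    sequence_id: str
    start: int
    end: int
    base: str
    flank5: Optional[str] = None
    flank3: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def scorable(self) -> bool:
        """True when both flanks are defined canonical bases."""
        return self.flank5 is not None and self.flank3 is not None

    def to_motif(self) -> BulgeMotif:
        """Motif of a +1 insertion at this run (one extra repeat on the
        bulged strand, so n = run length + 1)."""
        if not self.scorable:
            raise MotifError(
                f"run {self.sequence_id}:{self.start}-{self.end} touches a "
                "sequence boundary or ambiguous base; flanks undefined"
            )
        return BulgeMotif(self.flank5, self.base, self.flank3, self.length + 1)


def find_runs(
    sequence: str, sequence_id: str = "", min_length: int = 1
) -> list[MicrosatelliteRun]:
    """Locate maximal homopolymer runs of length >= ``min_length``.

    Ambiguity codes (N etc.) terminate runs and never serve as flanks; a
    flank is left undefined at sequence boundaries or next to an ambiguous
    base, making the run non-scorable.
    """
    if min_length < 1:
        raise MotifError(f"min_length must be >= 1, got {min_length}")
    if not sequence:
        raise MotifError("empty sequence")
    seq = sequence.upper()
    runs: list[MicrosatelliteRun] = []
    i, L = 0, len(seq)
    while i < L:
        b = seq[i]
        if b not in BASES:
            i += 1
            continue
        j = i
        while j < L and seq[j] == b:
            j += 1
        if j - i >= min_length:
            f5 = seq[i - 1] if i > 0 and seq[i - 1] in BASES else None
            f3 = seq[j] if j < L and seq[j] in BASES else None
            runs.append(MicrosatelliteRun(sequence_id, i, j, b, f5, f3))
        i = j
    return runs


def scan_fasta(
    path, min_length: int = 4
) -> Iterator[MicrosatelliteRun]:
    """Yield homopolymer runs from every record of a FASTA file."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        yield from find_runs(str(record.seq), record.id, min_length)
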