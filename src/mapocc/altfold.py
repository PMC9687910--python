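"""Single-stem hairpin detection in RNA segments.

When an r-protein that clamps an rRNA helix dissociates, the freed
strand can re-pair locally into a non-native stem-loop that competes
with the native secondary structure.  Deciding whether a strand
segment *can* form such a hairpin needs only the simplest model: one
contiguous stem of Watson-Crick (AU, GC) and optionally wobble (GU)
pairs closed by a loop of at least ``min_loop`` nucleotides.  Internal
mismatches terminate the stem — no bulges, no thermodynamics; full
minimum-free-energy folding is out of scope on purpose.

The best hairpin maximizes stem length, breaking ties by smaller loop
and then by the 5'-most closing position.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["Hairpin", "best_hairpin", "WC_PAIRS", "WOBBLE_PAIRS"]

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
DEFAULT_MIN_LOOP = 3


@dataclass
class Hairpin:
    """A contiguous stem-loop: pairs (i, j) with i < j, outermost first."""

    sequence: str
    pairs: list[tuple[int, int]]

    @property
    def stem_length(self) -> int:
        return len(self.pairs)

    @property
    def loop_length(self) -> int:
        i, j = self.pairs[-1]  # innermost pair
        return j - i - 1

    def dot_bracket(self) -> str:
        chars = ["." for _ in self.sequence]
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def _pair_set(allow_wobble: bool) -> set[tuple[str, str]]:
    return WC_PAIRS | WOBBLE_PAIRS if allow_wobble else set(WC_PAIRS)


def best_hairpin(
    seq: str,
    min_loop: int = DEFAULT_MIN_LOOP,
    allow_wobble: bool = True,
) -> Hairpin | None:
    """Longest single-stem hairpin of a sequence, or None below 2 bp.

    For every candidate outer pair (i, j) the stem extends inward
    through consecutive complementary pairs while the enclosed loop
    stays at least ``min_loop`` long; the first mismatch (or the loop
    limit) terminates it.  Among all candidates the longest stem wins;
    ties go to the smaller loop, then to the smallest ``i``.
    """
    seq = seq.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValidationError(f"invalid RNA characters {sorted(bad)}")
    if len(seq) < min_loop + 2:
        raise ValidationError(
            f"sequence length {len(seq)} below min_loop + 2 = {min_loop + 2}"
        )
    pairs_ok = _pair_set(allow_wobble)
    n = len(seq)
    best: tuple[int, int, int] | None = None  # (-stem, loop, i) minimized
    best_pairs: list[tuple[int, int]] | None = None
    for i in range(n - min_loop - 1):
        for j in range(i + min_loop + 1, n):
            stem: list[tuple[int, int]] = []
            a, b = i, j
            while b - a - 1 >= min_loop and (seq[a], seq[b]) in pairs_ok:
                stem.append((a, b))
                a += 1
                b -= 1
            if len(stem) < 2:
                continue
            ii, jj = stem[-1]
            key = (-len(stem), jj - ii - 1, i)
            if best is None or key < best:
                best = key
                best_pairs = stem
    if best_pairs is None:
        return None
    return Hairpin(seq, best_pairs)
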