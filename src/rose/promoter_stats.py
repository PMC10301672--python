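"""Nucleotide preferences at the +1 (initiating) and -1 positions.

Bacterial transcription initiates preferentially at purines (A/G) while the
base directly upstream of the start site favors pyrimidines (C/T); these
summaries quantify that preference over a promoter set.  Entries whose
relevant base is N are excluded from the denominators and counted
separately, so the reported fractions always partition {A,C,G,T}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ParameterError
from .motif_discovery import PromoterSequence

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class NucleotidePreference:
    position_label: str  # "+1" or "-1"
    fractions: dict[str, float]
    n: int
    n_excluded: int

    @property
    def purine_fraction(self) -> float:
        return self.fractions["A"] + self.fractions["G"]

    @property
    def pyrimidine_fraction(self) -> float:
        return self.fractions["C"] + self.fractions["T"]

    def as_dict(self) -> dict:
        return {
            "position": self.position_label,
            **{b: self.fractions[b] for b in "ACGT"},
            "purine": self.purine_fraction,
            "pyrimidine": self.pyrimidine_fraction,
            "n": self.n,
            "n_excluded": self.n_excluded,
        }


def _preference(bases: list[str], label: str) -> NucleotidePreference:
    kept = [b for b in bases if b in "ACGT"]
    excluded = len(bases) - len(kept)
    if not kept:
        raise ParameterError(f"no unambiguous {label} bases to summarize")
    counts = Counter(kept)
    n = len(kept)
    fractions = {b: counts.get(b, 0) / n for b in "ACGT"}
    pref = NucleotidePreference(label, fractions, n, excluded)
    assert abs(sum(fractions.values()) - 1.0) < 1e-9
    assert abs(pref.purine_fraction + pref.pyrimidine_fraction - 1.0) < 1e-9
    return pref


def nucleotide_preferences(
    promoters: list[PromoterSequence],
) -> tuple[NucleotidePreference, NucleotidePreference]:
    """Exact base-frequency summaries at +1 and -1 over a promoter set."""
    if not promoters:
        raise ParameterError("no promoters given")
    plus1 = _preference([p.plus1 for p in promoters], "+1")
    minus1 = _preference([p.minus1 for p in promoters], "-1")
    return plus1, minus1
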