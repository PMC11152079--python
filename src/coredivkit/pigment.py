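"""Six-locus genetic model of cowpea seed-coat pigmentation pattern and color.

Three patterning loci (Pat9.1 on Vu09, Pat10.1 and Pat10.2 on Vu10) and
three color loci (Col3.1 on Vu03, Col5.1 on Vu05, Col6.1 on Vu06) jointly
determine the seed-coat phenotype of inbred lines.  Each locus is biallelic
and, matching cowpea's selfing biology, only homozygous states are modeled;
a genotype is summarised by one allele letter per locus.  The map returns
the set of phenotype rows a genotype satisfies: a unique row gives that
label, several give "ambiguous" with the candidate set attached.

The large-eye and Holstein rows require the same allele combination
(A, T, C); the map deliberately surfaces this overlap rather than
resolving it, and callers that need a single label (e.g. the simulator)
resolve via an explicit priority list.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

AMBIGUOUS = "ambiguous"

#: Locus -> tag SNP on the genotyping array.
TAG_SNPS = {
    "Pat9.1": "2_01960",
    "Pat10.1": "2_31919",
    "Pat10.2": "2_15395",
    "Col3.1": "2_20787",
    "Col5.1": "2_19309",
    "Col6.1": "2_22603",
}

#: Locus -> chromosome of the tag SNP.
LOCUS_CHROM = {
    "Pat9.1": "Vu09",
    "Pat10.1": "Vu10",
    "Pat10.2": "Vu10",
    "Col3.1": "Vu03",
    "Col5.1": "Vu05",
    "Col6.1": "Vu06",
}

#: Allowed (homozygous) allele states per locus.
ALLELES = {
    "Pat9.1": ("A", "G"),
    "Pat10.1": ("C", "T"),
    "Pat10.2": ("C", "T"),
    "Col3.1": ("G", "T"),
    "Col5.1": ("C", "T"),
    "Col6.1": ("C", "T"),
}

PATTERN_LOCI = ("Pat9.1", "Pat10.1", "Pat10.2")
COLOR_LOCI = ("Col3.1", "Col5.1", "Col6.1")

#: Pattern rows: label -> required allele(s) per patterning locus.
PATTERN_RULES: dict[str, dict[str, set]] = {
    "full coat": {"Pat9.1": {"G"}, "Pat10.1": {"T"}, "Pat10.2": {"C"}},
    "small eye": {"Pat9.1": {"A"}, "Pat10.1": {"C"}, "Pat10.2": {"T", "C"}},
    "large eye": {"Pat9.1": {"A"}, "Pat10.1": {"T"}, "Pat10.2": {"C"}},
    "Holstein": {"Pat9.1": {"A"}, "Pat10.1": {"T"}, "Pat10.2": {"C"}},
    "Watson": {"Pat9.1": {"G"}, "Pat10.1": {"C"}, "Pat10.2": {"T", "C"}},
}

#: Color rows: label -> required allele(s); white additionally requires the
#: patterning allele Pat10.1 = C.
COLOR_RULES: dict[str, dict[str, set]] = {
    "black": {"Col3.1": {"G"}, "Col5.1": {"C"}, "Col6.1": {"T"}},
    "red": {"Col3.1": {"T"}, "Col5.1": {"C", "T"}, "Col6.1": {"T"}},
    "tan": {"Col3.1": {"G"}, "Col5.1": {"T"}, "Col6.1": {"T"}},
    "blue": {"Col3.1": {"G"}, "Col5.1": {"C"}, "Col6.1": {"C"}},
    "white": {"Pat10.1": {"C"}, "Col3.1": {"G"}, "Col5.1": {"C", "T"}, "Col6.1": {"T"}},
}

PATTERN_LEVELS = tuple(PATTERN_RULES) + (AMBIGUOUS,)
COLOR_LEVELS = tuple(COLOR_RULES) + (AMBIGUOUS,)


@dataclass(frozen=True)
class PigmentGenotype:
    """Homozygous allele state at each of the six pigmentation loci."""

    Pat9_1: str
    Pat10_1: str
    Pat10_2: str
    Col3_1: str
    Col5_1: str
    Col6_1: str

    def __post_init__(self):
        for locus, value in self.as_dict().items():
            if value not in ALLELES[locus]:
                raise ValueError(
                    f"{locus} allele must be one of {ALLELES[locus]}, got {value!r}"
                )

    def as_dict(self) -> dict[str, str]:
        return {
            "Pat9.1": self.Pat9_1,
            "Pat10.1": self.Pat10_1,
            "Pat10.2": self.Pat10_2,
            "Col3.1": self.Col3_1,
            "Col5.1": self.Col5_1,
            "Col6.1": self.Col6_1,
        }


def _matching(rules: dict[str, dict[str, set]], genotype: dict[str, str]) -> list[str]:
    hits = []
    for label, req in rules.items():
        if all(genotype[locus] in allowed for locus, allowed in req.items()):
            hits.append(label)
    return hits


def pattern_from_genotype(pg: PigmentGenotype) -> tuple[str, list[str]]:
    """Pattern label for a genotype: (label, candidate rows matched).

    The label is the unique matched row, AMBIGUOUS when several rows match,
    or AMBIGUOUS with an empty candidate list when none does.
    """
    hits = _matching(PATTERN_RULES, pg.as_dict())
    return (hits[0] if len(hits) == 1 else AMBIGUOUS), hits


def color_from_genotype(pg: PigmentGenotype) -> tuple[str, list[str]]:
    """Color label for a genotype, same convention as the pattern map."""
    hits = _matching(COLOR_RULES, pg.as_dict())
    return (hits[0] if len(hits) == 1 else AMBIGUOUS), hits


def resolve_label(candidates: list[str], priority: list[str]) -> str:
    """First candidate in ``priority`` order; AMBIGUOUS if none listed."""
    for label in priority:
        if label in candidates:
            return label
    return AMBIGUOUS


def enumerate_model_table() -> pd.DataFrame:
    """Exhaustive genotype -> phenotype table over all 2^6 homozygous states.

    Columns: the six locus alleles, pattern/color labels, the candidate
    sets, and per-row ambiguity flags.  The frame carries summary counts in
    ``attrs`` (unambiguous / ambiguous / unmatched, per trait).
    """
    loci = PATTERN_LOCI + COLOR_LOCI
    rows = []
    for alleles in product(*(ALLELES[l] for l in loci)):
        geno = dict(zip(loci, alleles))
        pg = PigmentGenotype(*[geno[l] for l in loci])
        pat, pat_hits = pattern_from_genotype(pg)
        col, col_hits = color_from_genotype(pg)
        rows.append(
            {
                **geno,
                "pattern": pat,
                "pattern_candidates": tuple(pat_hits),
                "color": col,
                "color_candidates": tuple(col_hits),
            }
        )
    table = pd.DataFrame(rows)
    for trait in ("pattern", "color"):
        cand = table[f"{trait}_candidates"].map(len)
        table.attrs[f"{trait}_unambiguous"] = int((cand == 1).sum())
        table.attrs[f"{trait}_ambiguous"] = int((cand > 1).sum())
        table.attrs[f"{trait}_unmatched"] = int((cand == 0).sum())
    return table
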