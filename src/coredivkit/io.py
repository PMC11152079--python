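"""Genotype and phenotype I/O and the central genotype data model.

The package works on biallelic SNP-array genotypes held as a samples x
variants dosage matrix counting copies of allele A1 (0, 1, 2) with a single
missing sentinel.  Genotypes are exchanged on disk as PLINK 1 binary triples
(BED/BIM/FAM, SNP-major v1.0 layout); phenotypes and sample metadata travel
as TSV with header.  All allele labels are kept as written in the BIM --
frequencies are always recomputed downstream, never trusted from file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Kept distinct from 0/1/2 through
#: every operation; nothing in the package silently imputes over it except
#: where a method explicitly requires complete data (PCA, kinship), and then
#: only in a local working copy.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (SNP-major, low bits first within a byte):
#   00 -> homozygous A1 (dosage 2), 01 -> missing, 10 -> het, 11 -> hom A2.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a PLINK binary triple is malformed or inconsistent."""


def chromosome_sort_key(name: str) -> tuple:
    """Sort key for chromosome labels: alphabetic prefix, then numeric suffix.

    "Vu02" < "Vu10" numerically even though "Vu10" < "Vu2" lexicographically.
    Labels without a numeric suffix sort after those with one, by full name.
    """
    m = re.match(r"^(.*?)(\d+)$", str(name))
    if m:
        return (m.group(1), 0, int(m.group(2)), "")
    return (str(name), 1, 0, str(name))


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant and sample metadata.

    dosages[i, j] counts copies of allele A1 of variant j carried by sample
    i; the value set is {0, 1, 2, MISSING}.  ``variants`` has columns
    (id, chrom, pos, a1, a2); ``samples`` has at least a column ``id``.
    Variants are kept sorted by (chromosome, position).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- basic facts -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_variants)

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage matrix is {self.dosages.shape} but tables declare "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        vals = np.unique(self.dosages)
        bad = set(vals.tolist()) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"illegal dosage values: {sorted(bad)}")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive (1-based)")
        if (self.variants["a1"] == self.variants["a2"]).any():
            raise ValueError("a1 == a2 at some variant")

    def is_sorted(self) -> bool:
        keys = [
            (chromosome_sort_key(c), p)
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]
        return all(keys[k] <= keys[k + 1] for k in range(len(keys) - 1))

    def sort_variants(self) -> "GenotypeMatrix":
        """Return a copy with variants sorted by (chromosome, position)."""
        order = sorted(
            range(self.n_variants),
            key=lambda j: (
                chromosome_sort_key(self.variants["chrom"].iat[j]),
                self.variants["pos"].iat[j],
            ),
        )
        return self.take_variants(np.asarray(order))

    # -- subsetting --------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_variant_ids(self, ids) -> "GenotypeMatrix":
        keep = set(ids)
        idx = np.flatnonzero(self.variants["id"].isin(keep).to_numpy())
        return self.take_variants(idx)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.variants[["id", "chrom", "pos", "a1", "a2"]]
            .reset_index(drop=True)
            .equals(other.variants[["id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True))
            and self.samples["id"].reset_index(drop=True).equals(
                other.samples["id"].reset_index(drop=True)
            )
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary triple
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 binary triple into a :class:`GenotypeMatrix`.

    ``bed_path`` may be a prefix (``bim_path``/``fam_path`` omitted) or the
    explicit ``.bed`` path.  Dosage counts copies of the BIM's first allele
    (A1).  Variants are returned sorted by (chromosome, position).
    """
    bed_path = Path(bed_path)
    if bim_path is None and fam_path is None:
        prefix = bed_path.with_suffix("") if bed_path.suffix == ".bed" else bed_path
        bed_path = prefix.with_suffix(".bed")
        bim_path = prefix.with_suffix(".bim")
        fam_path = prefix.with_suffix(".fam")
    bim_path, fam_path = Path(bim_path), Path(fam_path)

    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise PlinkFormatError(f"missing file: {p}")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "id", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "id": str},
    )
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not PLINK v1.0 SNP-major)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload is {len(raw) - 3} bytes, expected "
            f"{bytes_per_variant}*{m} for {n} samples x {m} variants"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, low pair first
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T  # samples x variants

    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    samples = pd.DataFrame({"id": fam["id"]})
    g = GenotypeMatrix(dosages, variants, samples)
    return g if g.is_sorted() else g.sort_variants()


def write_plink(g: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Write ``g`` as a PLINK 1 binary triple; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    n, m = g.shape
    bytes_per_variant = (n + 3) // 4
    enc = np.zeros_like(g.dosages, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        enc[g.dosages == dosage] = code
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = enc.T
    out = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    bed_path.write_bytes(_BED_MAGIC + out.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "a1": g.variants["a1"],
            "a2": g.variants["a2"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.samples["id"],
            "id": g.samples["id"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Phenotypes and sample metadata
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-sample trait values after encoding.

    ``data`` is indexed by sample id.  Quantitative traits are real-valued
    columns; each qualitative trait is expanded into one 0/1 indicator
    column per observed level, named ``trait.level``.  ``kinds`` maps every
    emitted column to "quantitative" or "qualitative"; ``source_trait``
    maps indicator columns back to the original trait name.
    """

    data: pd.DataFrame
    kinds: dict = field(default_factory=dict)
    source_trait: dict = field(default_factory=dict)

    def traits(self, kind: str | None = None) -> list[str]:
        cols = list(self.data.columns)
        if kind is None:
            return cols
        return [c for c in cols if self.kinds.get(c) == kind]


def read_phenotypes(path, trait_spec: dict, known_ids=None) -> PhenotypeTable:
    """Read a TSV phenotype table and encode traits.

    ``trait_spec`` maps column names to "quantitative" or "qualitative".
    Qualitative traits are dummy-coded into one binary indicator per level
    (missing cells stay missing in every indicator).  ``known_ids``, when
    given, is used to flag rows whose sample id is unmatched (retained,
    with a warning).
    """
    import warnings

    raw = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA", ""])
    if "id" not in raw.columns:
        raise ValueError("phenotype TSV must have an 'id' column")
    if known_ids is not None:
        unmatched = ~raw["id"].isin(set(known_ids))
        if unmatched.any():
            warnings.warn(
                f"{int(unmatched.sum())} phenotype rows have unknown sample ids; retained"
            )
    return encode_trait_table(raw.set_index("id"), trait_spec)


def encode_trait_table(raw: pd.DataFrame, trait_spec: dict) -> PhenotypeTable:
    """Encode an in-memory raw trait frame per ``trait_spec`` (see above)."""
    data = {}
    kinds: dict = {}
    source: dict = {}
    for trait, kind in trait_spec.items():
        if trait not in raw.columns:
            raise KeyError(f"trait {trait!r} not present")
        col = raw[trait]
        if kind == "quantitative":
            try:
                vals = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(
                    f"non-numeric value in quantitative trait {trait!r} at row {row}"
                ) from exc
            data[trait] = vals.astype(float)
            kinds[trait] = "quantitative"
            source[trait] = trait
        elif kind == "qualitative":
            levels = sorted(col.dropna().astype(str).unique())
            for lev in levels:
                name = f"{trait}.{lev}"
                ind = (col.astype(str) == lev).astype(float)
                ind[col.isna()] = np.nan
                data[name] = ind
                kinds[name] = "qualitative"
                source[name] = trait
            if not levels:  # all-missing column retained, zero observations
                name = trait
                data[name] = pd.Series(np.nan, index=raw.index)
                kinds[name] = "qualitative"
                source[name] = trait
        else:
            raise ValueError(f"unknown trait kind {kind!r} for {trait!r}")
    return PhenotypeTable(pd.DataFrame(data, index=raw.index), kinds, source)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (id, region, germplasm_status, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""])
    if "id" not in meta.columns:
        raise ValueError("metadata TSV must have an 'id' column")
    return meta
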