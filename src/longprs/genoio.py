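"""Genotype and weight-table I/O, allele harmonization and coverage accounting.

Genotypes live in a :class:`GenotypeMatrix`: a sample x variant matrix of
counted-allele dosages in [0, 2] (``NaN`` marks missing calls) plus a variant
table. Weight tables ("summary statistics") are plain :class:`pandas.DataFrame`
objects with the columns ``chrom, pos, id, effect_allele, other_allele, beta``
and optionally ``p`` and ``freq``; ``beta`` is the per-counted-allele effect on
the log-odds scale.

Harmonization aligns a weight table to a genotype panel by (chrom, pos),
resolving allele orientation (direct / swapped / strand-complemented /
swapped + complemented), dropping strand-ambiguous A/T and C/G pairs, and
accounting for every input variant in a :class:`CoverageReport`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["chrom", "pos", "id", "effect_allele", "other_allele", "beta"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class VariantRecord:
    """One biallelic SNV: 1-based position, counted and other allele."""

    chrom: str
    pos: int
    id: str
    counted_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        self.counted_allele = self.counted_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.counted_allele == self.other_allele:
            raise ValueError(f"identical alleles at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with variant metadata.

    ``dosage[i, j]`` is the number of copies (possibly fractional, from
    imputation) of ``variants.counted_allele[j]`` carried by sample ``i``;
    ``NaN`` marks a missing genotype. ``variants`` has columns
    ``chrom, pos, id, counted_allele, other_allele`` and, when imputation
    quality is known, ``impq`` in [0, 1].
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and (obs.min() < -1e-9 or obs.max() > 2 + 1e-9):
            raise ValueError("observed dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        keys = list(
            zip(self.variants["chrom"], self.variants["pos"],
                self.variants["counted_allele"], self.variants["other_allele"])
        )
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, alleles) keys in panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the genotype call is missing."""
        return np.isnan(self.dosage)

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per variant from non-missing samples."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def filled(self) -> np.ndarray:
        """Dosage with missing entries mean-imputed (2 x allele frequency)."""
        out = self.dosage.copy()
        fill = 2.0 * self.allele_freq()
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[1]]
        return out

    def subset_variants(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def subset_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants.copy(),
            dosage=self.dosage[index, :],
        )


@dataclass
class CoverageReport:
    """Accounting of weight-table variants retained after harmonization."""

    n_input: int
    n_covered: int
    reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_covered > self.n_input:
            raise ValueError("n_covered exceeds n_input")
        dropped = sum(self.reasons.values())
        if dropped != self.n_input - self.n_covered:
            raise ValueError("drop-reason tallies do not reconcile")

    @property
    def percent(self) -> float:
        return coverage_percent(self.n_covered, self.n_input)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"field": "n_input", "value": self.n_input},
                {"field": "n_covered", "value": self.n_covered},
                {"field": "percent", "value": self.percent}]
        rows += [{"field": f"dropped_{k}", "value": v}
                 for k, v in sorted(self.reasons.items())]
        return pd.DataFrame(rows)


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at the given decimal place (table style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def coverage_percent(n_covered: int, n_input: int, decimals: int = 2) -> float:
    """Percent of input variants covered, rounded half-up.

    Two decimals by default (Table style); pass ``decimals=1`` for
    prose-style percentages.
    """
    if n_input <= 0:
        raise ValueError("n_input must be positive")
    if not 0 <= n_covered <= n_input:
        raise ValueError("n_covered must lie in [0, n_input]")
    return round_half_up(100.0 * n_covered / n_input, decimals)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Dosage is the DS field when present, otherwise the ALT-allele count from
    GT; missing GT becomes NaN. Multiallelic and non-SNV records are skipped
    with a logged count. The counted allele is ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    cols = []
    impq = []
    any_impq = False
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            n_skipped += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:  # DS absent from the FORMAT header
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = rec.gt_types.astype(float)
            dos = np.where(gt == 3, 2.0, gt)
            dos[rec.gt_types == 2] = np.nan
        rows.append(dos)
        r2 = rec.INFO.get("R2")
        impq.append(np.nan if r2 is None else float(r2))
        if r2 is not None:
            any_impq = True
        cols.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}", alt, ref))
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNV records", n_skipped)
    variants = pd.DataFrame(
        cols, columns=["chrom", "pos", "id", "counted_allele", "other_allele"]
    )
    if any_impq:
        variants["impq"] = impq
    dosage = (np.array(rows).T if rows
              else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write hard-called genotypes as VCF 4.2 (bgzipped when path ends in .gz).

    Fractional dosages are rounded to the nearest allele count for the GT
    field; NaN becomes ``./.``.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    chroms = list(dict.fromkeys(gm.variants["chrom"]))
    for c in chroms:
        buf.write(f"##contig=<ID={c}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(gm.samples) + "\n")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, v in gm.variants.iterrows():
        dos = gm.dosage[:, j]
        calls = []
        for d in dos:
            if np.isnan(d):
                calls.append("./.")
            else:
                calls.append(gt_codes[int(round(d))])
        buf.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t"
                  f"{v.counted_allele}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
    text = buf.getvalue()
    if str(path).endswith(".gz"):
        import pysam

        plain = str(path)[:-3]
        with open(plain, "w") as fh:
            fh.write(text)
        pysam.tabix_compress(plain, str(path), force=True)
        import os

        os.remove(plain)
    else:
        with open(path, "w") as fh:
            fh.write(text)


DEFAULT_DIALECT = {
    "chrom": "chrom", "pos": "pos", "id": "id",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "beta": "beta", "p": "p", "freq": "freq", "or": "OR",
}


def read_weight_table(path, dialect: dict | None = None,
                      sep: str = "\t") -> pd.DataFrame:
    """Read a delimited weight table, mapping columns through ``dialect``.

    ``dialect`` maps canonical names (chrom, pos, id, effect_allele,
    other_allele, beta, p, freq, or) to the file's column names. An OR column
    is converted to beta by log; a row carrying both beta and OR is rejected
    (and logged) when they disagree by more than 1e-6 after exponentiation.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        log.warning("read_weight_table: empty file %s", path)
        return pd.DataFrame(columns=WEIGHT_COLUMNS)
    if raw.empty:
        log.warning("read_weight_table: no rows in %s", path)
        return pd.DataFrame(columns=WEIGHT_COLUMNS)

    has_beta = d["beta"] in raw.columns
    has_or = d["or"] in raw.columns
    mandatory = ["chrom", "pos", "effect_allele", "other_allele"]
    for key in mandatory:
        if d[key] not in raw.columns:
            raise FormatError(f"missing mandatory column {d[key]!r}")
    if not has_beta and not has_or:
        raise FormatError(f"missing effect column {d['beta']!r} (or {d['or']!r})")

    out = pd.DataFrame({
        "chrom": raw[d["chrom"]].astype(str),
        "pos": raw[d["pos"]].astype(int),
        "id": (raw[d["id"]].astype(str) if d["id"] in raw.columns
               else raw[d["chrom"]].astype(str) + ":" + raw[d["pos"]].astype(str)),
        "effect_allele": raw[d["effect_allele"]].astype(str).str.upper(),
        "other_allele": raw[d["other_allele"]].astype(str).str.upper(),
    })
    if has_beta:
        out["beta"] = raw[d["beta"]].astype(float)
    else:
        out["beta"] = np.log(raw[d["or"]].astype(float))
    if has_beta and has_or:
        inconsistent = (
            (np.exp(out["beta"]) - raw[d["or"]].astype(float)).abs() > 1e-6
        )
        if inconsistent.any():
            log.warning(
                "read_weight_table: rejected %d rows with inconsistent beta/OR",
                int(inconsistent.sum()),
            )
            out = out[~inconsistent.values]
    if d["p"] in raw.columns:
        out["p"] = raw.loc[out.index, d["p"]].astype(float)
    if d["freq"] in raw.columns:
        out["freq"] = raw.loc[out.index, d["freq"]].astype(float)
    bad = ~np.isfinite(out["beta"])
    if bad.any():
        log.warning("read_weight_table: rejected %d rows with non-finite beta",
                    int(bad.sum()))
        out = out[~bad.values]
    return out.reset_index(drop=True)


def write_weight_table(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def complement_allele(a: str) -> str:
    return _COMPLEMENT[a]


def is_ambiguous_pair(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (palindromic) allele pairs: A/T and C/G."""
    return (a1, a2) in _AMBIGUOUS_PAIRS


def harmonize(weights: pd.DataFrame, gm: GenotypeMatrix,
              drop_ambiguous: bool = True) -> tuple[pd.DataFrame, CoverageReport]:
    """Align a weight table to a genotype panel.

    Variants are matched by (chrom, pos); alleles are compared directly, then
    swapped (beta negated, effect allele switched), then strand-complemented,
    then swapped + complemented. Strand-ambiguous A/T and C/G weights are
    dropped when ``drop_ambiguous``; repeated positions collapse to the first
    occurrence. The returned table carries ``panel_index`` (column in
    ``gm.dosage``) with ``effect_allele`` equal to the panel's counted allele.
    """
    panel = {}
    for j, v in gm.variants.iterrows():
        panel[(str(v.chrom), int(v.pos))] = (j, v.counted_allele, v.other_allele)

    reasons = {"absent": 0, "allele_mismatch": 0, "ambiguous": 0, "duplicate": 0}
    seen: set[tuple[str, int]] = set()
    kept_rows = []
    for _, w in weights.iterrows():
        key = (str(w.chrom), int(w.pos))
        ea, oa = w.effect_allele, w.other_allele
        if drop_ambiguous and is_ambiguous_pair(ea, oa):
            reasons["ambiguous"] += 1
            continue
        if key not in panel:
            reasons["absent"] += 1
            continue
        if key in seen:
            reasons["duplicate"] += 1
            continue
        j, counted, other = panel[key]
        if len(ea) != 1 or len(oa) != 1 or ea not in _COMPLEMENT or oa not in _COMPLEMENT:
            reasons["allele_mismatch"] += 1
            continue
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (ea, oa) == (counted, other):
            beta, flip = w.beta, False
        elif (ea, oa) == (other, counted):
            beta, flip = -w.beta, True
        elif (cea, coa) == (counted, other):
            beta, flip = w.beta, False
        elif (cea, coa) == (other, counted):
            beta, flip = -w.beta, True
        else:
            reasons["allele_mismatch"] += 1
            continue
        seen.add(key)
        row = {
            "chrom": str(w.chrom), "pos": int(w.pos), "id": str(w.id),
            "effect_allele": counted, "other_allele": other,
            "beta": float(beta), "panel_index": j,
        }
        if "p" in weights.columns:
            row["p"] = float(w.p)
        if "freq" in weights.columns:
            row["freq"] = (1.0 - float(w.freq)) if flip else float(w.freq)
        kept_rows.append(row)

    harmonized = pd.DataFrame(
        kept_rows,
        columns=WEIGHT_COLUMNS + ["panel_index"]
        + [c for c in ("p", "freq") if c in weights.columns],
    )
    report = CoverageReport(
        n_input=len(weights), n_covered=len(harmonized),
        reasons={k: v for k, v in reasons.items() if v},
    )
    return harmonized, report
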