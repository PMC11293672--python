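"""Per-line allele-frequency tables: data model, I/O and descriptive summaries.

The canonical interchange format is a UTF-8 tab-separated table with header
``chrom<TAB>pos<TAB><line1>...<lineN>``; ``.`` encodes a missing allele
frequency.  Coordinates are 1-based and inclusive throughout the package; any
BED-style export converts explicitly.

The experimental design is 8 closed lines: 4 selected ("HR", High Runner) and
4 non-selected control ("C") lines, with allele frequencies per line obtained
either from pooled sequencing or from pooling individual genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineDesign",
    "AFTable",
    "read_af_table",
    "write_af_table",
    "intersect_shared_loci",
    "maf_summary",
    "fixation_stats",
]

HR = "HR"
C = "C"


class AFValidationError(ValueError):
    """An allele-frequency table violates its invariants."""


@dataclass(frozen=True)
class LineDesign:
    """Ordered line identifiers and their linetype (HR = selected, C = control)."""

    lines: tuple[str, ...]
    linetypes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lines) != len(self.linetypes):
            raise AFValidationError("lines and linetypes differ in length")
        if len(set(self.lines)) != len(self.lines):
            raise AFValidationError("duplicate line ids in design")
        bad = set(self.linetypes) - {HR, C}
        if bad:
            raise AFValidationError(f"unknown linetypes: {sorted(bad)}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def hr_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.linetypes) if t == HR])

    @property
    def c_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.linetypes) if t == C])

    def is_balanced_4v4(self) -> bool:
        return len(self.hr_indices) == 4 and len(self.c_indices) == 4

    @classmethod
    def default(cls) -> "LineDesign":
        """The experiment's design: 4 HR lines and 4 C lines."""
        return cls(
            lines=("HR1", "HR2", "HR3", "HR4", "C1", "C2", "C3", "C4"),
            linetypes=(HR, HR, HR, HR, C, C, C, C),
        )


@dataclass
class AFTable:
    """Loci x lines matrix of allele frequencies with design metadata.

    ``af`` holds values in [0, 1]; missing values are ``nan``.  Loci are kept
    sorted by (chrom, pos) and unique.
    """

    chrom: np.ndarray  # object/str array, shape (n_loci,)
    pos: np.ndarray  # int64, 1-based
    af: np.ndarray  # float64, shape (n_loci, n_lines)
    design: LineDesign
    generation: int | None = None

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def validate(self) -> "AFTable":
        if self.af.shape != (self.n_loci, self.design.n_lines):
            raise AFValidationError(
                f"af shape {self.af.shape} does not match "
                f"{self.n_loci} loci x {self.design.n_lines} lines"
            )
        if self.n_loci and self.pos.min() < 1:
            i = int(np.argmin(self.pos))
            raise AFValidationError(
                f"position must be >= 1 at ({self.chrom[i]}, {self.pos[i]})"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.af < 0) | (self.af > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise AFValidationError(
                f"allele frequency {self.af[i, j]} outside [0, 1] at "
                f"({self.chrom[i]}, {self.pos[i]}) line {self.design.lines[j]}"
            )
        key = pd.MultiIndex.from_arrays([self.chrom, self.pos])
        if key.has_duplicates:
            dup = key[key.duplicated()][0]
            raise AFValidationError(f"duplicate locus {dup}")
        return self

    def sort(self) -> "AFTable":
        order = np.lexsort((self.pos, self.chrom))
        return replace(
            self, chrom=self.chrom[order], pos=self.pos[order], af=self.af[order]
        )

    def take(self, idx: np.ndarray) -> "AFTable":
        return replace(self, chrom=self.chrom[idx], pos=self.pos[idx], af=self.af[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for j, line in enumerate(self.design.lines):
            df[line] = self.af[:, j]
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, design: LineDesign, generation: int | None = None
    ) -> "AFTable":
        missing = [l for l in design.lines if l not in df.columns]
        if missing:
            raise AFValidationError(f"design lines absent from table: {missing}")
        extra = [c for c in df.columns if c not in ("chrom", "pos", *design.lines)]
        if extra:
            raise AFValidationError(f"columns not in design: {extra}")
        t = cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            af=df[list(design.lines)].to_numpy(dtype=np.float64),
            design=design,
            generation=generation,
        )
        return t.sort().validate()


def read_af_table(
    path, design: LineDesign, generation: int | None = None
) -> AFTable:
    """Read the canonical AF TSV, validate, and return a sorted table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, na_values=["."],
        float_precision="round_trip",
    )
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise AFValidationError("AF table must start with 'chrom' and 'pos' columns")
    return AFTable.from_frame(df, design, generation=generation)


def write_af_table(table: AFTable, path) -> None:
    """Write the canonical AF TSV (inverse of :func:`read_af_table`)."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep=".")  # str() = shortest repr


def read_af_table_vcf(
    path, design: LineDesign, generation: int | None = None
) -> AFTable:
    """Convenience reader: per-sample AF from a multi-sample VCF with AD fields.

    Each VCF sample column must be named after a design line; AF is computed as
    alt allele depth / total depth from the AD field of biallelic records.  The
    TSV dialect remains the canonical interchange format.
    """
    import pysam  # optional dependency, imported lazily

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    missing = [l for l in design.lines if l not in samples]
    if missing:
        raise AFValidationError(f"design lines absent from VCF: {missing}")
    chroms, poss, rows = [], [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        row = []
        for line in design.lines:
            ad = rec.samples[line].get("AD")
            if ad is None or ad[0] is None:
                row.append(np.nan)
                continue
            dp = sum(a for a in ad if a is not None)
            row.append(ad[1] / dp if dp > 0 else np.nan)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        rows.append(row)
    t = AFTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        af=np.array(rows, dtype=np.float64).reshape(len(rows), design.n_lines),
        design=design,
        generation=generation,
    )
    return t.sort().validate()


def intersect_shared_loci(a: AFTable, b: AFTable) -> tuple[AFTable, AFTable]:
    """Restrict both tables to loci with identical (chrom, pos), same order."""
    ka = pd.MultiIndex.from_arrays([a.chrom, a.pos])
    kb = pd.MultiIndex.from_arrays([b.chrom, b.pos])
    shared = ka.intersection(kb)  # sorted
    if len(shared) == 0:
        warnings.warn("no shared loci between tables", stacklevel=2)
    ia = ka.get_indexer(shared)
    ib = kb.get_indexer(shared)
    return a.take(ia), b.take(ib)


def _minor(af: np.ndarray) -> np.ndarray:
    return np.minimum(af, 1.0 - af)


def maf_summary(table: AFTable, window_bp: int) -> pd.DataFrame:
    """Windowed mean minor-allele frequency per linetype.

    Per chromosome and non-overlapping ``window_bp`` window, the mean over all
    loci and lines of a linetype of ``min(af, 1 - af)``.  Empty windows are
    absent from the output; windows where every value is missing yield ``nan``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    win = (table.pos - 1) // window_bp
    maf = _minor(table.af)
    df = pd.DataFrame(
        {
            "chrom": table.chrom,
            "window": win,
            "maf_hr": np.nanmean(maf[:, table.design.hr_indices], axis=1)
            if len(table.design.hr_indices)
            else np.nan,
            "maf_c": np.nanmean(maf[:, table.design.c_indices], axis=1)
            if len(table.design.c_indices)
            else np.nan,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = df.groupby(["chrom", "window"], sort=True).agg(
            maf_hr=("maf_hr", "mean"), maf_c=("maf_c", "mean"), n_loci=("maf_hr", "size")
        )
    out = out.reset_index()
    out["start"] = out["window"] * window_bp + 1
    out["end"] = (out["window"] + 1) * window_bp
    return out[["chrom", "start", "end", "n_loci", "maf_hr", "maf_c"]]


def fixation_stats(table: AFTable, regions: Sequence) -> dict:
    """Per-line fixed fraction over in-region loci, with an HR-vs-C Welch test.

    A locus counts as fixed in a line when its AF is exactly 0 or 1 (missing
    values are skipped locus-wise).  Returns per-line fractions and the
    unequal-variance T-test p-value comparing the HR lines' fractions with the
    control lines' (nan when the test is undefined, e.g. zero variance in both
    groups).
    """
    from scipy import stats

    if not regions:
        raise ValueError("regions must be non-empty")
    mask = np.zeros(table.n_loci, dtype=bool)
    for r in regions:
        hit = (table.chrom == r.chrom) & (table.pos >= r.start) & (table.pos <= r.end)
        if not hit.any():
            warnings.warn(
                f"region {r.chrom}:{r.start}-{r.end} contains no loci; excluded",
                stacklevel=2,
            )
        mask |= hit
    af = table.af[mask]
    fixed = (af == 0.0) | (af == 1.0)
    valid = ~np.isnan(af)
    with np.errstate(invalid="ignore"):
        frac = fixed.sum(axis=0) / valid.sum(axis=0)
    hr = frac[table.design.hr_indices]
    c = frac[table.design.c_indices]
    if np.ptp(hr) == 0 and np.ptp(c) == 0:
        p = np.nan  # zero variance in both groups: T undefined
    else:
        p = float(stats.ttest_ind(hr, c, equal_var=False).pvalue)
    return {
        "per_line": dict(zip(table.design.lines, frac)),
        "hr_mean": float(np.mean(hr)),
        "c_mean": float(np.mean(c)),
        "welch_p": p,
        "n_loci": int(mask.sum()),
    }
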