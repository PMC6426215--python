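"""Shared containers and call coding for the genotype pipeline.

Genotype calls use a symmetric parental coding on int8:

* ``PARENT_A = -1`` — homozygous for the parent-A allele
* ``PARENT_B = +1`` — homozygous for the parent-B allele
* ``HET      =  0`` — heterozygous (in a DH population this is a
  genotyping artefact, never a true state)
* ``MISSING  = -9`` — no call

On export to the conventional {0, 1, 2} dosage coding, parent A maps to 0,
het to 1, parent B to 2 and missing to an empty cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARENT_A = np.int8(-1)
PARENT_B = np.int8(1)
HET = np.int8(0)
MISSING = np.int8(-9)

#: states that count as a genotype call (not missing)
CALLED = (-1, 0, 1)

_TO_DOSAGE = {-1: 0, 0: 1, 1: 2}
_FROM_DOSAGE = {0: PARENT_A, 1: HET, 2: PARENT_B}


@dataclass
class GenotypeMatrix:
    """A line x SNP call matrix plus its ordered marker map.

    ``marker_map`` must have columns ``marker``, ``chrom``, ``pos_cM`` with
    rows ordered by (chromosome, position); its row order defines the
    column order of ``calls``.
    """

    calls: np.ndarray
    line_ids: list[str]
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D line x SNP matrix")
        if self.calls.shape[0] != len(self.line_ids):
            raise ValueError(
                f"{self.calls.shape[0]} rows but {len(self.line_ids)} line ids"
            )
        if self.calls.shape[1] != len(self.marker_map):
            raise ValueError(
                f"{self.calls.shape[1]} columns but {len(self.marker_map)} map rows"
            )
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(self.marker_map.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if self.marker_map["marker"].duplicated().any():
            dup = self.marker_map["marker"][self.marker_map["marker"].duplicated()]
            raise ValueError(f"duplicate marker ids: {list(dup[:5])}")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos_cM"].to_numpy(float)
            if np.any(np.diff(pos) < 0):
                raise ValueError("marker map positions not sorted within chromosome")
        bad = ~np.isin(self.calls, [PARENT_A, PARENT_B, HET, MISSING])
        if bad.any():
            raise ValueError(f"invalid call codes present: {np.unique(self.calls[bad])}")
        self.marker_map = self.marker_map.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.marker_map["marker"].tolist()

    def chromosomes(self) -> list:
        """Chromosome ids in map order (first-appearance order)."""
        return list(dict.fromkeys(self.marker_map["chrom"]))

    def chrom_slices(self) -> dict:
        """Map chromosome id -> slice of contiguous marker columns."""
        out = {}
        chrom = self.marker_map["chrom"].to_numpy()
        for c in self.chromosomes():
            idx = np.flatnonzero(chrom == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def subset(self, lines=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given line / SNP indices."""
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(li, si)],
            line_ids=[self.line_ids[int(i)] for i in li],
            marker_map=self.marker_map.iloc[si].reset_index(drop=True),
        )

    def to_dosage_frame(self) -> pd.DataFrame:
        """Lines x markers frame in {0, 1, 2} coding with NaN for missing."""
        out = np.where(
            self.calls == MISSING,
            np.nan,
            np.vectorize(_TO_DOSAGE.get, otypes=[float])(
                np.where(self.calls == MISSING, 0, self.calls)
            ),
        )
        return pd.DataFrame(out, index=self.line_ids, columns=self.marker_ids)


@dataclass
class BinMap:
    """Ordered marker bins with per-line consensus calls.

    ``bins`` has columns ``bin``, ``chrom``, ``first_marker``, ``last_marker``,
    ``n_snps``, ``pos_cM`` (and, after map estimation, ``d_cM``/``pos_est_cM``).
    ``bin_calls`` is a line x bin int8 matrix in the shared call coding.
    """

    bins: pd.DataFrame
    bin_calls: np.ndarray
    line_ids: list[str]
    members: list = field(default_factory=list)  # per bin: list of marker column idx

    def __post_init__(self) -> None:
        self.bin_calls = np.asarray(self.bin_calls, dtype=np.int8)
        if self.bin_calls.shape != (len(self.line_ids), len(self.bins)):
            raise ValueError("bin_calls shape does not match line ids / bin table")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def as_genotype_matrix(self) -> GenotypeMatrix:
        """View the bins as ordinary genetic markers."""
        mm = pd.DataFrame(
            {
                "marker": self.bins["bin"],
                "chrom": self.bins["chrom"],
                "pos_cM": self.bins["pos_cM"],
            }
        )
        return GenotypeMatrix(self.bin_calls, list(self.line_ids), mm)


def dosage_to_calls(frame: pd.DataFrame) -> np.ndarray:
    """Convert a {0, 1, 2}/NaN dosage frame back to int8 call codes."""
    arr = frame.to_numpy(dtype=float)
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    for dose, code in _FROM_DOSAGE.items():
        out[arr == dose] = code
    bad = ~np.isnan(arr) & ~np.isin(arr, [0.0, 1.0, 2.0])
    if bad.any():
        raise ValueError(f"invalid dosage values: {np.unique(arr[bad])[:5]}")
    return out
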