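"""Readers and writers for the pipeline's file formats.

All tables are comma-separated UTF-8.  Missing genotype calls are empty
cells in the {0, 1, 2} dosage coding ("." is never used as a missing
marker in numeric columns).  Genetic positions are cM floats.  Floats are
written with a fixed general format so identical runs produce
byte-identical files; run metadata (master seed, package version, row
counts) goes into a JSON sidecar manifest, never into data files.

VCF import/export is GT-only, unphased, biallelic (VCF 4.2); parsing uses
cyvcf2 when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GenotypeMatrix, BinMap, PARENT_A, PARENT_B, HET, MISSING, \
    dosage_to_calls
from .simulate import SimConfig, TruthBundle

FLOAT_FMT = "%.10g"

_GT_STR = {int(PARENT_A): "0/0", int(PARENT_B): "1/1", int(HET): "0/1",
           int(MISSING): "./."}


# ---------------------------------------------------------------------------
# genotype matrix


def write_genotype_csv(geno: GenotypeMatrix, geno_path, map_path) -> None:
    """Lines x markers CSV in {0, 1, 2} with empty cells for missing, plus
    a marker map CSV (marker, chrom, pos_cM)."""
    frame = geno.to_dosage_frame()
    out = frame.astype("Int64")  # nullable ints -> empty cells for missing
    out.index.name = "line"
    out.to_csv(geno_path)
    geno.marker_map.to_csv(map_path, index=False, float_format=FLOAT_FMT)


def read_genotype_csv(geno_path, map_path) -> GenotypeMatrix:
    frame = pd.read_csv(geno_path, index_col=0)
    marker_map = pd.read_csv(map_path)
    if marker_map["marker"].duplicated().any():
        dups = marker_map.loc[marker_map["marker"].duplicated(), "marker"]
        raise ValueError(f"duplicate marker ids in map: {list(dups[:5])}")
    if list(frame.columns) != marker_map["marker"].tolist():
        raise ValueError("genotype columns do not match marker map order")
    calls = dosage_to_calls(frame)
    return GenotypeMatrix(calls, [str(i) for i in frame.index], marker_map)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal GT-only unphased VCF 4.2; POS encodes cM * 10^4 (1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in geno.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.line_ids) + "\n")
        last = {}
        for j, row in geno.marker_map.iterrows():
            pos = int(round(row["pos_cM"] * 1e4)) + 1
            if pos <= last.get(row["chrom"], 0):  # enforce increasing POS
                pos = last[row["chrom"]] + 1
            last[row["chrom"]] = pos
            gts = "\t".join(_GT_STR[int(c)] for c in geno.calls[:, j])
            fh.write(f"{row['chrom']}\t{pos}\t{row['marker']}\tA\tG\t.\t.\t.\t"
                     f"GT\t{gts}\n")


def read_vcf(path, map_path=None) -> GenotypeMatrix:
    """Read a GT-only biallelic VCF.

    Calls map 0/0 -> parent A, 1/1 -> parent B, 0/1 -> het, ./. ->
    missing.  Multi-allelic sites are rejected (counted); an allele index
    beyond the ALT list raises an error naming the line and marker.  A
    marker map CSV gives cM positions; without one, POS/10^4 is used.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = []
    rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) > 1:
            n_multi += 1
            continue
        marker = v.ID or f"{v.CHROM}_{v.POS}"
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a = [x for x in g[:-1] if x is not None]
            if any(x > 1 for x in a):
                raise ValueError(
                    f"malformed GT token {'/'.join(map(str, g[:-1]))} for "
                    f"line {samples[i]} at marker {marker} (biallelic site)"
                )
            if not a or any(x < 0 for x in a):
                col[i] = MISSING
            elif all(x == 0 for x in a):
                col[i] = PARENT_A
            elif all(x == 1 for x in a):
                col[i] = PARENT_B
            else:
                col[i] = HET
        cols.append(col)
        rows.append({"marker": marker, "chrom": v.CHROM,
                     "pos_cM": (v.POS - 1) / 1e4})
    if n_multi:
        import logging
        logging.getLogger(__name__).warning(
            "read_vcf: rejected %d multi-allelic sites", n_multi)
    calls = np.column_stack(cols) if cols else np.zeros((len(samples), 0),
                                                        dtype=np.int8)
    marker_map = pd.DataFrame(rows)
    if map_path is not None:
        ext = pd.read_csv(map_path).set_index("marker")
        marker_map["pos_cM"] = ext.loc[marker_map["marker"], "pos_cM"].to_numpy()
        marker_map["chrom"] = ext.loc[marker_map["marker"], "chrom"].to_numpy()
    return GenotypeMatrix(calls, samples, marker_map)


def read_genotypes(path, fmt: str = "csv", map_path=None) -> GenotypeMatrix:
    """Dispatch on format ('csv' needs a map CSV; 'vcf' may take one)."""
    if fmt == "csv":
        if map_path is None:
            raise ValueError("CSV genotypes need a marker map")
        return read_genotype_csv(path, map_path)
    if fmt == "vcf":
        return read_vcf(path, map_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# plots, bins, BLUEs, truth


def write_plot_table(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_plot_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_binmap(binmap: BinMap, bins_path, calls_path) -> None:
    binmap.bins.to_csv(bins_path, index=False, float_format=FLOAT_FMT)
    frame = binmap.as_genotype_matrix().to_dosage_frame().astype("Int64")
    frame.index.name = "line"
    frame.to_csv(calls_path)


def read_binmap(bins_path, calls_path) -> BinMap:
    bins = pd.read_csv(bins_path)
    frame = pd.read_csv(calls_path, index_col=0)
    if list(frame.columns) != bins["bin"].tolist():
        raise ValueError("bin-call columns do not match bin table order")
    calls = dosage_to_calls(frame)
    return BinMap(bins=bins, bin_calls=calls,
                  line_ids=[str(i) for i in frame.index])


def write_blue_table(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, float_format=FLOAT_FMT)


def read_blue_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=[0, 1])


def write_truth(truth: TruthBundle, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh)


def read_truth(path) -> TruthBundle:
    with open(path) as fh:
        return TruthBundle.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# config and manifest


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data.get("simulation", data))


def load_run_config(path) -> dict:
    """Full pipeline config: 'simulation', 'binmap', 'cv' blocks (all
    optional; missing keys take the package defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("run config must be a mapping")
    return data


def write_manifest(path, seed: int, stages: dict) -> None:
    """Sidecar manifest: master seed, version and per-stage row counts."""
    with open(path, "w") as fh:
        json.dump({"package": "pgebv", "version": __version__,
                   "master_seed": int(seed), "stages": stages}, fh, indent=2,
                  sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
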