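"""Synthetic family-level genotype datasets for end-to-end testing.

Generates per-family dosage tables across independent SNPs from a
:class:`~triadglm.simulate.SimConfig`, optionally serialized as a plain TSV
or a PLINK bed/bim/fam fileset consumable by the genome scan.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cells import TRIAD_CELLS
from .design import ModelSpec, build_design
from .plink import write_bed, write_bim, write_fam
from .simulate import SimConfig, cell_distribution

__all__ = [
    "simulate_dose_table",
    "write_dose_tsv",
    "read_dose_tsv",
    "write_plink_fileset",
]

DOSE_COLUMNS = ["snp", "chrom", "pos", "family_id", "g_m", "g_f", "g_c"]


def simulate_dose_table(
    n_snps: int,
    config: SimConfig,
    spec: ModelSpec,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long-format per-family dosage table over independent SNPs.

    Each family unit is drawn per SNP from the triad cell distribution of the
    scenario; for dyad units the designated parent's dose is set missing
    (NaN).  Columns: snp, chrom, pos, family_id, g_m, g_f, g_c.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pi = cell_distribution(spec, config.true_effects, config.p2)
    x_m = np.array([c.x_m for c in TRIAD_CELLS], dtype=float)
    x_f = np.array([c.x_f for c in TRIAD_CELLS], dtype=float)
    x_c = np.array([c.x_c for c in TRIAD_CELLS], dtype=float)

    n_fam = config.n_triads + config.n_md + config.n_fd
    fam_ids = [f"F{i:05d}" for i in range(n_fam)]
    frames = []
    for s in range(n_snps):
        cells = rng.choice(len(TRIAD_CELLS), size=n_fam, p=pi)
        g_m, g_f, g_c = x_m[cells], x_f[cells].copy(), x_c[cells]
        g_f = g_f.copy()
        g_m = g_m.copy()
        # mask the father for md units, the mother for fd units
        md_lo = config.n_triads
        fd_lo = config.n_triads + config.n_md
        g_f[md_lo:fd_lo] = np.nan
        g_m[fd_lo:] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "snp": f"snp{s:05d}",
                    "chrom": "1",
                    "pos": (s + 1) * 1000,
                    "family_id": fam_ids,
                    "g_m": g_m,
                    "g_f": g_f,
                    "g_c": g_c,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_dose_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_dose_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "family_id": str})
    missing = set(DOSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"dose table missing columns: {sorted(missing)}")
    return table


def write_plink_fileset(table: pd.DataFrame, prefix) -> None:
    """Serialize a dose table as a PLINK bed/bim/fam fileset.

    One individual per family member; dyad units simply omit the missing
    parent, so the pedigree reader resolves them back to dyads.  A1 in the
    bim is the simulation's effect allele (label "A", reference "B"), and
    bed genotypes count A1 copies.
    """
    prefix = Path(prefix)
    snps = table["snp"].drop_duplicates().tolist()
    first = table[table["snp"] == snps[0]]

    individuals: list[tuple[str, str, str, str, str]] = []  # fid iid pat mat sex
    member_of: dict[tuple[str, str], int] = {}
    for _, row in first.iterrows():
        fid = row["family_id"]
        has_m = not pd.isna(row["g_m"])
        has_f = not pd.isna(row["g_f"])
        if has_m:
            member_of[(fid, "m")] = len(individuals)
            individuals.append((fid, f"{fid}_M", "0", "0", "2"))
        if has_f:
            member_of[(fid, "f")] = len(individuals)
            individuals.append((fid, f"{fid}_F", "0", "0", "1"))
        member_of[(fid, "c")] = len(individuals)
        individuals.append(
            (
                fid,
                f"{fid}_C",
                f"{fid}_F" if has_f else "0",
                f"{fid}_M" if has_m else "0",
                "0",
            )
        )

    doses = np.full((len(snps), len(individuals)), -1, dtype=np.int8)
    snp_index = {s: i for i, s in enumerate(snps)}
    for _, row in table.iterrows():
        s = snp_index[row["snp"]]
        fid = row["family_id"]
        for member, col in (("m", "g_m"), ("f", "g_f"), ("c", "g_c")):
            key = (fid, member)
            if key in member_of and not pd.isna(row[col]):
                doses[s, member_of[key]] = int(row[col])

    fam = pd.DataFrame(individuals, columns=["fid", "iid", "pat", "mat", "sex"])
    fam["pheno"] = "-9"
    bim_rows = table.drop_duplicates("snp")[["chrom", "snp", "pos"]].copy()
    bim = pd.DataFrame(
        {
            "chrom": bim_rows["chrom"].values,
            "snp": bim_rows["snp"].values,
            "cm": 0,
            "pos": bim_rows["pos"].values,
            "a1": "A",
            "a2": "B",
        }
    )
    write_fam(prefix.with_suffix(".fam"), fam)
    write_bim(prefix.with_suffix(".bim"), bim)
    write_bed(prefix.with_suffix(".bed"), doses)
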