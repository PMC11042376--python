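"""File formats: BED/BEDPE annotations, dense contact-map TSV, trajectories.

Coordinates are 0-based half-open throughout. Contact maps are gzipped
dense TSV with a single header line carrying chromosome name, length and
bin size; trajectories are one row per loop per frame.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chromatid import Conformation
from .contacts import ContactMap, PsCurve
from .extrusion import LoopTrajectory
from .kinetics import TimeSeries
from .synthetic import G2Fixture

__all__ = [
    "read_bed", "write_bed", "read_bedpe", "write_bedpe",
    "read_contact_map", "write_contact_map",
    "read_ps_curve", "write_ps_curve",
    "write_trajectory", "read_trajectory",
    "write_conformation", "read_conformation",
    "write_fixture", "read_fixture",
    "read_series",
]

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BEDPE_COLS[: min(df.shape[1], 6)] + [
        f"extra{i}" for i in range(max(df.shape[1] - 6, 0))
    ]
    return df


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    df[[c for c in BEDPE_COLS if c in df.columns]].to_csv(
        path, sep="\t", header=False, index=False)


def write_contact_map(cmap: ContactMap, path: str | Path,
                      chrom: str = "chr1") -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"#chrom={chrom}\tlength={cmap.chromosome_length}"
                 f"\tbin_size={cmap.bin_size}\tbalanced={int(cmap.balanced)}\n")
        np.savetxt(fh, cmap.matrix, fmt="%.6g", delimiter="\t")


def read_contact_map(path: str | Path) -> ContactMap:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().lstrip("#").strip()
        fields = dict(kv.split("=") for kv in header.split("\t"))
        matrix = np.loadtxt(fh, delimiter="\t")
    return ContactMap(matrix, int(fields["bin_size"]), int(fields["length"]),
                      balanced=bool(int(fields.get("balanced", 0))))


def write_ps_curve(ps: PsCurve, path: str | Path) -> None:
    pd.DataFrame({"s_bp": ps.s_bp, "p": ps.p}).to_csv(path, index=False)


def read_ps_curve(path: str | Path, bins_per_decade: float = 10.0) -> PsCurve:
    df = pd.read_csv(path)
    return PsCurve(df["s_bp"].to_numpy(), df["p"].to_numpy(), bins_per_decade)


def write_trajectory(traj: LoopTrajectory, path: str | Path) -> None:
    rows = []
    for frame in traj.frames:
        for (a, b), sp, st in zip(frame.loops, frame.species, frame.statuses):
            rows.append((frame.time_s, sp, int(a) * traj.site_bp,
                         int(b) * traj.site_bp, st))
        rows.append((frame.time_s, "_frame_meta", frame.anchored_cohesins,
                     frame.translocated_sites, str(frame.n_bound)))
    df = pd.DataFrame(rows, columns=["time_s", "species", "start_bp",
                                     "end_bp", "status"])
    df.to_csv(path, sep="\t", index=False,
              compression="gzip" if str(path).endswith(".gz") else None)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       compression="gzip" if str(path).endswith(".gz") else None)


def write_conformation(conf: Conformation, path: str | Path) -> None:
    df = pd.DataFrame({
        "bead_index": np.arange(conf.n_beads),
        "chromatid_id": conf.chromatid_id,
        "genomic_bp": conf.genomic_bp,
        "x_nm": conf.xyz[:, 0], "y_nm": conf.xyz[:, 1], "z_nm": conf.xyz[:, 2],
    })
    for name, flags in conf.annotations.items():
        df[name] = flags.astype(int)
    df.to_csv(path, index=False,
              compression="gzip" if str(path).endswith(".gz") else None)


def read_conformation(path: str | Path, bead_bp: int = 10_000) -> Conformation:
    df = pd.read_csv(path)
    ann_cols = [c for c in df.columns
                if c not in ("bead_index", "chromatid_id", "genomic_bp",
                             "x_nm", "y_nm", "z_nm")]
    return Conformation(
        genomic_bp=df["genomic_bp"].to_numpy(float),
        xyz=df[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
        bead_bp=bead_bp,
        chromatid_id=df["chromatid_id"].to_numpy(np.int32),
        annotations={c: df[c].to_numpy(bool) for c in ann_cols},
    )


def write_fixture(fixture: G2Fixture, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(fixture.to_dict(), fh)


def read_fixture(path: str | Path) -> G2Fixture:
    with open(path) as fh:
        return G2Fixture.from_dict(yaml.safe_load(fh))


def read_series(path: str | Path) -> TimeSeries:
    """CSV with columns time_min, value, unit (loop_kb|period_mb|area_fold)."""
    df = pd.read_csv(path)
    kinds = df["unit"].unique()
    if len(kinds) != 1:
        raise ValueError("series file mixes units")
    return TimeSeries(df["time_min"].to_numpy(float),
                      df["value"].to_numpy(float), str(kinds[0]))
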