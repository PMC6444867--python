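"""Plain-text readers and writers for the pipeline's tabular formats.

Everything the pipeline consumes or emits is TSV/BED/JSON so that runs are
inspectable and diffable: chrom.sizes tables, BED3 blacklists, staged bin
count tables, GC tracks, reference panels, droplet count tables, and the
clinical cohort table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinSet, GenomeBuild


def read_chrom_sizes(path: str | Path, name: str = "custom") -> GenomeBuild:
    """Read a chrom.sizes-style TSV (chrom, length) into a GenomeBuild."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no chromosomes")
    return GenomeBuild(name, tuple(zip(df["chrom"], df["length"])))


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3 file into (chrom, start, end) tuples; empty file is fine."""
    regions: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed3(path: str | Path, regions: list[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_bins(path: str | Path, binset: BinSet) -> None:
    binset.to_frame().to_csv(path, sep="\t", index=False)


def read_bins(path: str | Path, bin_size: int, build_name: str = "custom") -> BinSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return BinSet(
        chroms=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(dtype=np.int64),
        ends=df["end"].to_numpy(dtype=np.int64),
        usable=df["usable"].to_numpy().astype(bool),
        bin_size=bin_size,
        build_name=build_name,
    )


def write_counts(path: str | Path, binset: BinSet, values: np.ndarray,
                 sample_id: str, stage: str) -> None:
    """Write a staged per-bin value table. Stage is carried in a column so a
    file is self-describing."""
    df = binset.to_frame()
    df["sample_id"] = sample_id
    df["stage"] = stage
    df["value"] = values
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_counts(path: str | Path) -> tuple[str, str, np.ndarray]:
    """Read a staged count table; returns (sample_id, stage, values)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    sample_id = str(df["sample_id"].iloc[0])
    stage = str(df["stage"].iloc[0])
    return sample_id, stage, df["value"].to_numpy(dtype=float)


def write_gc_track(path: str | Path, binset: BinSet, gc: np.ndarray,
                   n_fraction: np.ndarray) -> None:
    df = binset.to_frame()
    df["gc"] = gc
    df["n_fraction"] = n_fraction
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gc_track(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df["gc"].to_numpy(dtype=float), df["n_fraction"].to_numpy(dtype=float)


def write_panel(tsv_path: str | Path, json_path: str | Path, panel,
                binset: BinSet) -> None:
    df = binset.to_frame()
    df["mean_pct"] = panel.mean_pct
    df["sd_pct"] = panel.sd_pct
    df["scorable"] = panel.scorable.astype(int)
    df.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    meta = {
        "n_controls": panel.n_controls,
        "build": binset.build_name,
        "bin_size": binset.bin_size,
        "n_bins": len(binset),
        "n_scorable": int(panel.scorable.sum()),
    }
    Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_panel(tsv_path: str | Path, json_path: str | Path):
    from .instability import ReferencePanel

    df = pd.read_csv(tsv_path, sep="\t", na_values=["NA"])
    meta = json.loads(Path(json_path).read_text())
    return ReferencePanel(
        n_controls=int(meta["n_controls"]),
        mean_pct=df["mean_pct"].to_numpy(dtype=float),
        sd_pct=df["sd_pct"].to_numpy(dtype=float),
        scorable=df["scorable"].to_numpy().astype(bool),
    )


def write_profile(tsv_path: str | Path, json_path: str | Path, profile,
                  binset: BinSet) -> None:
    df = binset.to_frame()
    df["z"] = profile.z
    df["call"] = profile.calls
    df.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    summary = {
        "sample_id": profile.sample_id,
        "i_score": profile.i_score,
        "s_score": profile.s_score,
        "threshold": profile.threshold,
        "n_gain": int(np.sum(profile.calls == "gain")),
        "n_loss": int(np.sum(profile.calls == "loss")),
    }
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def write_circos_track(path: str | Path, binset: BinSet, z: np.ndarray) -> None:
    """Export per-bin Z-scores as a Circos-ready TSV (chrom, start, end, z)."""
    df = pd.DataFrame({
        "chrom": binset.chroms, "start": binset.starts,
        "end": binset.ends, "z": z,
    })
    df = df[np.isfinite(df["z"].to_numpy(dtype=float))]
    df.to_csv(path, sep="\t", index=False, header=False)


def read_droplet_counts(path: str | Path) -> pd.DataFrame:
    """Droplet count table: sample_id, k_target, n_target, k_ref, n_ref."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "k_target", "n_target", "k_ref", "n_ref"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical cohort TSV, one row per subject.

    Required columns: id, best_response, ttp_months, ttp_event, os_months,
    os_event.  Biomarker and covariate columns are free-form.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "best_response", "ttp_months", "ttp_event",
                "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    return df
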