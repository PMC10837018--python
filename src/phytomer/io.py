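"""File formats and pipeline plumbing.

Canonical tabular dialect is TSV with a header row (UTF-8, decimal
point).  Genotypes travel as VCF 4.x (GT field only) or dosage TSV;
intervals as BED3+ (0-based half-open); profiles and traits as TSV.
Lengths are centimetres, coordinates base pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GenotypeMatrix, InternodeProfile

logger = logging.getLogger("phytomer")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_trait_tsv",
    "read_bed",
    "read_labels_tsv",
    "RunConfig",
    "run_pipeline",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix (GT field only).

    Multiallelic and non-SNP records are skipped (the count is logged);
    missing genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, ids, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        gt = var.genotype.array()[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    geno = GenotypeMatrix(
        accession_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        dosage=np.array(rows).T if rows else np.empty((len(samples), 0)),
        snp_ids=np.array(ids, dtype=object),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )
    geno.n_multiallelic_skipped = n_skipped
    return geno


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal diploid VCF (CHROM, POS, ID, REF, ALT, GT)."""
    path = Path(path)
    ref = geno.ref if geno.ref is not None else np.full(geno.n_snps, "A", dtype=object)
    alt = geno.alt if geno.alt is not None else np.full(geno.n_snps, "T", dtype=object)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(geno.chrom):  # preserves order
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accession_ids)
            + "\n"
        )
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(geno.n_snps):
            gts = "\t".join(
                "./." if np.isnan(x) else code[x] for x in geno.dosage[:, j]
            )
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t"
                f"{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: one row per SNP (snp, chrom, pos, then one column per accession)."""
    df = pd.DataFrame(geno.dosage.T, columns=geno.accession_ids)
    df.insert(0, "pos", geno.pos)
    df.insert(0, "chrom", geno.chrom)
    df.insert(0, "snp", geno.snp_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("snp", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"dosage TSV missing required column {col!r}")
    acc = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
    return GenotypeMatrix(
        accession_ids=acc,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        dosage=df[acc].to_numpy(dtype=float).T,
        snp_ids=df["snp"].to_numpy(dtype=object),
    )


def write_profile_tsv(profiles: list[InternodeProfile], path: str | Path) -> None:
    rows = [
        {
            "plant_id": p.plant_id,
            "genotype_id": p.genotype_id,
            "axis_kind": p.axis_kind,
            "internode_index": i + 1,
            "length_cm": float(L),
        }
        for p in profiles
        for i, L in enumerate(p.lengths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> list[InternodeProfile]:
    """Profile TSV -> InternodeProfile list; rejects negative lengths and
    duplicate (plant, index) rows, naming the offending row."""
    df = pd.read_csv(path, sep="\t")
    required = {"plant_id", "genotype_id", "axis_kind", "internode_index", "length_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile TSV missing column(s): {', '.join(sorted(missing))}")
    bad = df.index[df["length_cm"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive length_cm at row {int(bad[0]) + 2} (1-based incl. header)")
    if df.duplicated(["plant_id", "internode_index"]).any():
        dup = df[df.duplicated(["plant_id", "internode_index"])].iloc[0]
        raise ValueError(f"duplicate internode_index {dup['internode_index']} for plant {dup['plant_id']}")
    profiles = []
    for (pid, gid, kind), grp in df.groupby(
        ["plant_id", "genotype_id", "axis_kind"], sort=False
    ):
        grp = grp.sort_values("internode_index")
        profiles.append(
            InternodeProfile(
                plant_id=str(pid),
                genotype_id=str(gid),
                lengths=grp["length_cm"].to_numpy(),
                axis_kind=str(kind),
            )
        )
    return profiles


def read_trait_tsv(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        if df[index_col].duplicated().any():
            dup = df[index_col][df[index_col].duplicated()].iloc[0]
            raise ValueError(f"duplicate id {dup!r} in column {index_col!r}")
        df = df.set_index(index_col)
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ (0-based, half-open); zero/negative-length intervals are rejected."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name"]
    df.columns = names[: df.shape[1]] + [f"extra{k}" for k in range(df.shape[1] - 4)] if df.shape[1] > 4 else names[: df.shape[1]]
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"empty/negative BED interval at line {int(bad[0]) + 1}")
    return df


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (accession, label) -> Series indexed by accession."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels TSV needs two columns: accession, label")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="label")


# ---------------------------------------------------------------------------
# pipeline runner


_STAGES = ("simulate", "traits", "pst-fst")

_DEFAULTS = {
    "seed": 7,
    "stages": ["simulate", "traits", "pst-fst"],
    "out_dir": "phytomer_run",
    "log_level": "INFO",
    "simulate": {"n_genotypes": 200, "reps_per_genotype": 4},
    "pst_fst": {"n_boot": 1000, "target_fst": 0.1, "n_snps": 5000, "n_per_subpop": 100},
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration; unknown keys are rejected."""

    seed: int = 7
    stages: list = field(default_factory=lambda: list(_STAGES))
    out_dir: str = "phytomer_run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=lambda: dict(_DEFAULTS["simulate"]))
    pst_fst: dict = field(default_factory=lambda: dict(_DEFAULTS["pst_fst"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        merged = {**_DEFAULTS, **raw}
        for k in ("simulate", "pst_fst"):
            merged[k] = {**_DEFAULTS[k], **(raw.get(k) or {})}
        return cls(**merged)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "stages": list(self.stages),
                    "out_dir": str(self.out_dir),
                    "log_level": self.log_level,
                    "simulate": dict(self.simulate),
                    "pst_fst": dict(self.pst_fst),
                },
                fh,
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Each stochastic stage consumes a deterministic sub-seed derived from
    the run seed; a resolved copy of the config and a machine-readable
    JSON summary are written next to the outputs.
    """
    from . import culm, popgen, synthetic

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "config.resolved.yaml")
    ss = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % 2**31) for name, s in
           zip(_STAGES, ss.spawn(len(_STAGES)))}
    summary: dict = {"seed": config.seed, "stages": {}}
    profiles = None
    try:
        if "simulate" in config.stages:
            cfg = synthetic.PhytomerSimConfig(seed=sub["simulate"], **config.simulate)
            profiles = synthetic.gen_phytomer_population(cfg)
            write_profile_tsv(profiles, out / "profiles.tsv")
            summary["stages"]["simulate"] = {"n_profiles": len(profiles)}
        if "traits" in config.stages:
            if profiles is None:
                raise RuntimeError("traits stage requires the simulate stage")
            records = [culm.derive_traits(p) for p in profiles]
            tbl = pd.DataFrame([vars(r) for r in records])
            tbl.to_csv(out / "trait_records.tsv", sep="\t", index=False)
            til = tbl.rename(columns={"genotype_id": "genotype"})
            til["replicate"] = til["plant_id"].str.rsplit("_", n=1).str[-1]
            vc = culm.estimate_repeatability(til.assign(value=til["TIL"]))
            summary["stages"]["traits"] = {
                "n_records": len(records),
                "TIL_repeatability_W2": vc.W2,
                "TIL_lrt_p": vc.lrt_p,
            }
        if "pst-fst" in config.stages:
            p = config.pst_fst
            gcfg = synthetic.StructuredGenotypeConfig(
                seed=sub["pst-fst"],
                target_fst=p["target_fst"], n_snps=p["n_snps"],
                n_per_subpop=p["n_per_subpop"],
            )
            geno, labels = synthetic.gen_structured_genotypes(gcfg)
            fst = popgen.weir_cockerham_fst(geno, labels, ("pop1", "pop2"))
            tcfg = synthetic.DivergentTraitConfig(
                seed=sub["pst-fst"] + 1, n_per_subpop=p["n_per_subpop"]
            )
            values, tlabels = synthetic.gen_divergent_traits(tcfg)
            pst = popgen.bootstrap_pst(
                values, tlabels, ("pop1", "pop2"),
                n_boot=p["n_boot"], seed=sub["pst-fst"] + 2,
            )
            summary["stages"]["pst-fst"] = {
                "fst_weighted": fst.weighted,
                "pst": pst.pst,
                "pst_ci": [pst.ci_lower, pst.ci_upper],
                "verdict": popgen.pst_fst_verdict(pst, fst),
            }
    except Exception as exc:  # halt with stage name and cause
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
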