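"""Satellitome catalog assembly, summary statistics and pipeline orchestration.

The catalog is the classic per-family metrics table of a satellitome study:
one row per family with unit length, genome-proportion abundance, total bp,
copy number, mean divergence, AT content, superfamily label, DIVPEAK, RPS
and distribution class. A transcription of the published bread-wheat
catalog ships with the package (``satkit/data/wheat_satellitome.tsv``; 34 families,
decimal commas normalized, divergence stored as percent) and drives the
printed-number checks of the summary statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import compare_map, landscape as landscape_mod, mining, monomer as monomer_mod, synthetic


@dataclass
class SatFamilyRecord:
    name: str
    unit_length: int
    abundance_pct: float
    total_bp: int
    n_copies: int
    divergence_pct: float
    at_percent: float
    sf_label: str | None
    divpeak: int | None
    rps: float | None
    distribution: str


@dataclass
class SatellitomeSummary:
    n_families: int
    total_abundance_pct: float
    total_bp: int
    total_copies: int
    genome_size_mbp: float
    satellitome_mbp: float
    n_abundant: int          # abundance > 0.05% of the genome
    n_scarce: int            # abundance < 0.01%
    n_short: int             # unit < 100 bp
    n_long: int              # unit > 1000 bp
    n_at_rich: int           # AT > 50%
    n_superfamilies: int
    n_new_families: int | None
    min_divergence_pct: float
    max_divergence_pct: float


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def copies_from_bp(total_bp: int, unit_length: int) -> int:
    """Catalog convention: copy number = total bp / unit length, half-up."""
    return round_half_up(total_bp / unit_length)


def load_published_catalog() -> pd.DataFrame:
    """The published 34-family bread-wheat catalog fixture."""
    path = files("satkit.data").joinpath("wheat_satellitome.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"sf": "string"})
    df["sf"] = df["sf"].where(df["sf"].notna(), None)
    return df


def published_catalog_checksum() -> str:
    return hashlib.sha256(files("satkit.data").joinpath("wheat_satellitome.tsv").read_bytes()).hexdigest()


def records_from_dataframe(df: pd.DataFrame) -> list[SatFamilyRecord]:
    return [
        SatFamilyRecord(
            r["name"], int(r["unit_length"]), float(r["abundance_pct"]), int(r["total_bp"]),
            int(r["n_copies"]), float(r["divergence_pct"]), float(r["at_pct"]),
            r["sf"] if isinstance(r["sf"], str) else None,
            int(r["divpeak"]), float(r["rps"]), r["distribution"],
        )
        for _, r in df.iterrows()
    ]


def build_catalog(monomers: dict[str, str],
                  landscapes: dict[str, "landscape_mod.RepeatLandscape"],
                  structures: dict[str, "monomer_mod.MonomerStructureReport"],
                  distributions: dict[str, "compare_map.DistributionCall"],
                  sf_labels: dict[str, str | None],
                  total_bp_basis: int,
                  name_prefix: str = "Sat") -> list[SatFamilyRecord]:
    """Assemble one record per family from the per-stage outputs.

    Families are renamed ``<prefix>NN-<len>`` ordered by descending
    abundance; total bp = genome proportion x the stated sequence basis;
    copy number = total bp / unit length rounded half-up.
    """
    for fam in monomers:
        for stage, mapping in (("landscape", landscapes), ("structure", structures),
                               ("distribution", distributions)):
            if fam not in mapping:
                raise KeyError(f"missing {stage} output for family {fam!r}")
    order = sorted(monomers, key=lambda f: -landscapes[f].total_abundance)
    records = []
    for rank, fam in enumerate(order, start=1):
        ls = landscapes[fam]
        seq = monomers[fam]
        total_bp = int(round(ls.total_abundance * total_bp_basis))
        mean_div = ls.mean_divergence()
        records.append(
            SatFamilyRecord(
                name=f"{name_prefix}{rank:02d}-{len(seq)}",
                unit_length=len(seq),
                abundance_pct=100.0 * ls.total_abundance,
                total_bp=total_bp,
                n_copies=copies_from_bp(total_bp, len(seq)),
                divergence_pct=100.0 * mean_div if mean_div is not None else float("nan"),
                at_percent=structures[fam].at_percent or float("nan"),
                sf_label=sf_labels.get(fam),
                divpeak=ls.divpeak,
                rps=ls.rps,
                distribution=distributions[fam].label,
            )
        )
    return records


def summarize(catalog: list[SatFamilyRecord], genome_size_mbp: float,
              known_families=None) -> SatellitomeSummary:
    """Headline satellitome statistics from catalog columns alone.

    ``known_families`` may be a count of previously described families
    (plain subtraction) or a list of their monomer sequences (matched to the
    catalog is not possible from records alone, so sequence matching is done
    in :func:`count_known_families` and the resulting count passed here).
    """
    if not catalog:
        raise ValueError("empty catalog")
    if genome_size_mbp <= 0:
        raise ValueError("genome size must be positive")
    total_ab = sum(r.abundance_pct for r in catalog)
    n_known = known_families if isinstance(known_families, int) else None
    return SatellitomeSummary(
        n_families=len(catalog),
        total_abundance_pct=total_ab,
        total_bp=sum(r.total_bp for r in catalog),
        total_copies=sum(r.n_copies for r in catalog),
        genome_size_mbp=genome_size_mbp,
        satellitome_mbp=total_ab / 100.0 * genome_size_mbp,
        n_abundant=sum(1 for r in catalog if r.abundance_pct > 0.05),
        n_scarce=sum(1 for r in catalog if r.abundance_pct < 0.01),
        n_short=sum(1 for r in catalog if r.unit_length < 100),
        n_long=sum(1 for r in catalog if r.unit_length > 1000),
        n_at_rich=sum(1 for r in catalog if r.at_percent > 50.0),
        n_superfamilies=len({r.sf_label for r in catalog if r.sf_label}),
        n_new_families=len(catalog) - n_known if n_known is not None else None,
        min_divergence_pct=min(r.divergence_pct for r in catalog),
        max_divergence_pct=max(r.divergence_pct for r in catalog),
    )


def count_known_families(monomers: dict[str, str], known_sequences: list[str],
                         min_identity: float = 80.0) -> int:
    """How many catalog families match a previously described monomer
    (rotational identity >= min_identity percent)."""
    n = 0
    for seq in monomers.values():
        if any(
            compare_map.rotational_alignment(seq, known).identity >= min_identity
            for known in known_sequences
        ):
            n += 1
    return n


def pearson(xs, ys) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p-value; (nan, nan) when a
    variable has zero variance or fewer than 3 points are given."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3 or len(xs) != len(ys):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def catalog_dataframe(catalog: list[SatFamilyRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in catalog])


# ---------------------------------------------------------------------------
# Whole-pipeline orchestration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "genome_mb": 5.0,
    "n_chromosomes": 4,
    "coverage": 1.2,
    "read_length": 151,
    "insert_mean": 350,
    "error_rate": 0.002,
    "rounds": 3,
    "pairs_per_round": None,
    "min_cluster_size": 10,
    "sample_pairs_landscape": None,
    "name_prefix": "SynSat",
}


def validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if cfg["rounds"] < 1:
        raise ValueError("rounds must be >= 1")
    if cfg["coverage"] <= 0:
        raise ValueError("coverage must be > 0")
    return cfg


def run_pipeline(config: dict | None, out_dir, seed: int = 0) -> dict:
    """simulate -> mine -> landscape -> structure -> map -> catalog.

    Writes catalog.tsv, summary.json, distribution_matrix.tsv and a
    manifest.json recording parameters and the seed; returns a dict with the
    in-memory stage outputs.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chromosomes = synthetic.default_chromosomes(cfg["genome_mb"], cfg["n_chromosomes"])
    genome_bp = sum(c.length for c in chromosomes)
    plans = synthetic.default_plans(genome_bp)
    te_lib = synthetic.load_te_library()
    genome, truth = synthetic.plant_genome(chromosomes, plans, int(rng.integers(2**31)),
                                           te_library=te_lib)
    pairs = synthetic.simulate_reads(
        genome, cfg["coverage"], cfg["read_length"], cfg["insert_mean"],
        cfg["error_rate"], int(rng.integers(2**31)),
    )
    truth.to_bed(out / "truth.bed")
    truth.to_json(out / "truth.json")

    mcfg = mining.MiningConfig(min_cluster_size=cfg["min_cluster_size"])
    monomers_found, rounds = mining.run_satminer(
        pairs, cfg["rounds"], cfg["pairs_per_round"], int(rng.integers(2**31)), mcfg
    )
    monomers = {m.name: m.sequence for m in monomers_found}
    synthetic.write_fasta(monomers, out / "monomers.fasta")

    landscapes, total_bp = landscape_mod.compute_landscapes(
        monomers, pairs, cfg["sample_pairs_landscape"], int(rng.integers(2**31))
    )
    structures = {fam: monomer_mod.structure_report(fam, seq) for fam, seq in monomers.items()}
    sf_labels = compare_map.group_superfamilies(monomers)

    distributions = {}
    arrays_by_family = {}
    for fam, seq in monomers.items():
        hits = compare_map.search_assembly(seq, genome)
        arrays = compare_map.merge_hits_to_arrays(hits, len(seq))
        arrays_by_family[fam] = arrays
        distributions[fam] = compare_map.classify_distribution(fam, arrays, chromosomes)

    catalog = build_catalog(monomers, landscapes, structures, distributions, sf_labels,
                            total_bp_basis=genome_bp, name_prefix=cfg["name_prefix"])
    df = catalog_dataframe(catalog)
    df.to_csv(out / "catalog.tsv", sep="\t", index=False)
    summary = summarize(catalog, genome_size_mbp=genome_bp / 1e6)
    (out / "summary.json").write_text(json.dumps(dataclasses.asdict(summary), indent=1))

    matrix = pd.DataFrame(
        [
            {"family": fam, "class": distributions[fam].label,
             **{c.name: sum(1 for a in arrays_by_family[fam] if a.chromosome == c.name)
                for c in chromosomes}}
            for fam in monomers
        ]
    )
    matrix.to_csv(out / "distribution_matrix.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "config": cfg,
        "mining": dataclasses.asdict(mcfg),
        "n_read_pairs": len(pairs),
        "n_families_found": len(monomers),
        "published_catalog_checksum": published_catalog_checksum(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "chromosomes": chromosomes, "plans": plans, "genome": genome, "truth": truth,
        "pairs": pairs, "monomers": monomers_found, "rounds": rounds,
        "landscapes": landscapes, "structures": structures, "sf_labels": sf_labels,
        "distributions": distributions, "arrays": arrays_by_family,
        "catalog": catalog, "summary": summary,
    }
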