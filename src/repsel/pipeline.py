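"""End-to-end pipeline: simulate → annotate → enrich → charge.

One run emulates a full selection experiment: an initial patient-derived
library plus four sublibraries enriched by biopanning (MBP, MOG, LMP-1 and
sequential LMP-1 then MBP), two chains each, at a configurable read depth.
The run plants ground-truth binder structure — antigen-specific clones,
polyreactive clones enriched by every antigen, cross-reactive clones shared
between MBP and LMP-1, and MOG binders drawn preferentially from
negative-charge CDR3s — then annotates and filters the reads, detects
enrichment outliers per (initial, sublibrary) pair, summarizes polyreactivity
and computes charge-profile shifts.

Everything is driven by one declarative :class:`RunConfig`; every output
table carries the seed and a config hash in its header, the manifest echoes
every setting and per-stage record tallies, and a rerun with the same config
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import AnnotatedRearrangement, VdjAnnotator, filter_annotations
from .charge import (SCHEMES, ChargeComparison, ChargeProfile,
                     charge_distribution, compare_profiles)
from .enrichment import (CdrCountTable, EnrichmentRecord, count_cdr3,
                         detect_outliers, enrichment_frame,
                         fit_selection_regression, polyreactivity_flags)
from .germline import GermlineSet, build_toy_germline, write_germline_fasta
from .io import (annotations_to_frame, write_fastq_pairs, write_report_table,
                 write_rearrangements)
from .merge import merge_batch
from .simulate import (Repertoire, apply_selection, assign_fitness, emit_reads,
                       simulate_repertoire)

__all__ = ["LibrarySpec", "RunConfig", "RunReport", "run_pipeline",
           "DEFAULT_LIBRARIES", "ANTIGENS"]

ANTIGENS = ("MBP", "MOG", "LMP1")

#: initial library plus the four enriched sublibraries (antigen, rounds)
DEFAULT_LIBRARIES: tuple["LibrarySpec", ...] = ()  # filled below
CHAINS = ("heavy", "light")


@dataclass(frozen=True)
class LibrarySpec:
    """A library: its name and the biopanning schedule that produced it.

    ``selections`` is a sequence of (antigen, rounds) applied in order; the
    initial library has an empty schedule.  Sequential double enrichment is a
    two-element schedule.
    """

    name: str
    selections: tuple[tuple[str, int], ...] = ()


DEFAULT_LIBRARIES = (
    LibrarySpec("MS"),
    LibrarySpec("MBP", (("MBP", 2),)),
    LibrarySpec("MOG", (("MOG", 2),)),
    LibrarySpec("LMP1", (("LMP1", 2),)),
    LibrarySpec("LMP1_MBP", (("LMP1", 2), ("MBP", 2))),
)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    All defaults are echoed into the manifest so no setting is implicit.
    ``reads_per_library`` is per chain.  ``write_reads`` additionally dumps
    the simulated FASTQ pairs and truth tables (reads are regenerated
    deterministically from the seed either way; the tables are the bundle's
    reproducibility contract).
    """

    seed: int = 0
    outdir: Path = Path("repsel_run")
    # simulation scale
    n_clones: int = 2000
    reads_per_library: int = 50_000
    read_len: int = 250
    error_rate: float = 0.001
    zipf_exponent: float = 1.1
    shm_rate: float = 0.005
    productive_fraction: float = 0.95
    # planted selection structure
    binders_per_antigen: int = 8
    binder_fitness: float = 20.0
    background_fitness_sigma: float = 0.05
    n_polyreactive: int = 2
    n_cross_reactive: int = 2
    # annotation & filtering
    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    min_v_identity: float = 70.0
    # enrichment & charge analysis
    alpha: float = 0.05
    transform: str = "anscombe"
    charge_scheme: str = "default"
    libraries: tuple[LibrarySpec, ...] = DEFAULT_LIBRARIES
    write_reads: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.libraries = tuple(
            lib if isinstance(lib, LibrarySpec)
            else LibrarySpec(lib["name"],
                             tuple((a, int(r)) for a, r in lib.get("selections", ())))
            for lib in self.libraries)
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")
        if not (0 < self.min_v_identity <= 100):
            raise ValueError("min_v_identity must be in (0, 100]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.charge_scheme not in SCHEMES:
            raise ValueError(f"unknown charge scheme {self.charge_scheme!r}")
        if not self.libraries or self.libraries[0].selections:
            raise ValueError("first library must be the unselected baseline")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self, include_outdir: bool = True) -> dict:
        d = asdict(self)
        d["outdir"] = str(d["outdir"])
        d["libraries"] = [{"name": lib.name,
                           "selections": [list(s) for s in lib.selections]}
                          for lib in self.libraries]
        if not include_outdir:
            d.pop("outdir")
        return d

    @property
    def config_hash(self) -> str:
        # outdir excluded: the same analysis in two directories is one config
        blob = json.dumps(self.to_dict(include_outdir=False), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """In-memory results of one pipeline run (files are under ``outdir``)."""

    config: RunConfig
    outdir: Path
    manifest: dict
    germline: GermlineSet
    repertoires: dict[str, Repertoire]
    planted: dict[str, dict[str, list[str]]]  # chain -> antigen/“poly”/“cross” -> ids
    count_tables: dict[tuple[str, str], CdrCountTable]
    enrichment: dict[tuple[str, str], list[EnrichmentRecord]]
    polyreactivity: dict[str, "object"]
    charge_profiles: dict[tuple[str, str], ChargeProfile]
    charge_comparisons: dict[tuple[str, str], ChargeComparison]


def _child_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed) % 2**31, *tags])
    return int(ss.generate_state(1)[0] % 2**31)


def _plant_binders(rep: Repertoire, config: RunConfig,
                   chain_idx: int) -> dict[str, list[str]]:
    """Assign per-antigen fitness with planted binder structure.

    Polyreactive clones bind every antigen; cross-reactive clones bind MBP and
    LMP-1 (and therefore enrich in the sequential LMP-1/MBP library); MOG
    binders are the most negatively charged eligible clones (CDR3 net charge
    ≤ −2, most negative first) so MOG selection shifts the charge profile
    toward strong negative values.  Top-10 abundance ranks are excluded from
    planting so the baseline is never dominated by a binder.
    """
    from .charge import DEFAULT_SCHEME, net_charge

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed % 2**31, 7, chain_idx]))
    eligible = [c for c in rep.clones[10:] if c.productive and c.cdr3_aa]
    order = list(rng.permutation(len(eligible)))
    pool = [eligible[i] for i in order]

    def take(n: int, prefer_key=None) -> list[str]:
        chosen: list[str] = []
        if prefer_key is not None:
            ranked = sorted((c for c in pool if prefer_key(c) is not None),
                            key=prefer_key)
            for clone in ranked[:n]:
                chosen.append(clone.clone_id)
                pool.remove(clone)
        while len(chosen) < n and pool:
            chosen.append(pool.pop(0).clone_id)
        return chosen

    def mog_key(clone):
        # most negative CDR3s first, mirroring the strong-negative shift
        # selection on MOG produces; clones above −2 are not preferred
        charge = net_charge(clone.cdr3_aa, DEFAULT_SCHEME)
        return charge if charge <= -2 else None

    poly = take(config.n_polyreactive)
    cross = take(config.n_cross_reactive)
    planted: dict[str, list[str]] = {"polyreactive": poly, "cross_reactive": cross}
    for antigen in ANTIGENS:
        specific = take(config.binders_per_antigen,
                        mog_key if antigen == "MOG" else None)
        planted[antigen] = specific
        ids = set(specific) | set(poly)
        if antigen in ("MBP", "LMP1"):
            ids |= set(cross)
        assign_fitness(rep, antigen, clone_ids=sorted(ids),
                       value=config.binder_fitness,
                       background_sigma=config.background_fitness_sigma,
                       rng_seed=_child_seed(config.seed, 8, chain_idx,
                                            ANTIGENS.index(antigen)))
    return planted


def _select(rep: Repertoire, spec: LibrarySpec) -> Repertoire:
    for antigen, rounds in spec.selections:
        rep = apply_selection(rep, antigen, rounds)
    return rep


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full five-library, two-chain analysis.

    Writes, under ``config.outdir``: the germline reference, per-(library,
    chain) rearrangement and CDR3-count tables and charge profiles, per-pair
    enrichment tables, per-chain polyreactivity summaries, per-pair charge
    comparisons, and ``manifest.json`` with config echo and per-stage record
    tallies.  Any stage failure aborts with the stage name; partial outputs
    are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash,
            "repsel_version": __version__}
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash,
                      "repsel_version": __version__,
                      "config": config.to_dict(include_outdir=False),
                      "stages": {}, "planted": {}}
    stage = "build_germline"
    try:
        germline = build_toy_germline(seed=config.seed % 2**31)
        write_germline_fasta(germline, outdir / "germline.fasta")

        annotator = VdjAnnotator(germline)
        repertoires: dict[str, Repertoire] = {}
        planted: dict[str, dict[str, list[str]]] = {}
        count_tables: dict[tuple[str, str], CdrCountTable] = {}
        profiles: dict[tuple[str, str], ChargeProfile] = {}
        scheme = SCHEMES[config.charge_scheme]

        stage = "simulate_repertoire"
        for ci, chain in enumerate(CHAINS):
            rep = simulate_repertoire(
                germline, config.n_clones,
                rng_seed=_child_seed(config.seed, 1, ci), chain=chain,
                zipf_exponent=config.zipf_exponent,
                productive_fraction=config.productive_fraction,
                shm_rate=config.shm_rate)
            planted[chain] = _plant_binders(rep, config, ci)
            repertoires[chain] = rep
        manifest["planted"] = planted

        for li, lib in enumerate(config.libraries):
            for ci, chain in enumerate(CHAINS):
                stage = f"emit_reads[{lib.name},{chain}]"
                rep = _select(repertoires[chain], lib)
                batch = emit_reads(
                    rep, config.reads_per_library,
                    error_rate=config.error_rate, read_len=config.read_len,
                    rng_seed=_child_seed(config.seed, 2, li, ci),
                    library_id=lib.name, min_overlap=config.min_overlap)
                if config.write_reads:
                    write_fastq_pairs(batch.pairs,
                                      outdir / f"{lib.name}_{chain}_R1.fastq",
                                      outdir / f"{lib.name}_{chain}_R2.fastq")
                    write_report_table(batch.truth,
                                       outdir / f"{lib.name}_{chain}_truth.tsv",
                                       meta)

                stage = f"annotate[{lib.name},{chain}]"
                merges = merge_batch(batch.pairs, config.min_overlap,
                                     config.max_mismatch_frac)
                records: list[AnnotatedRearrangement] = []
                for pair, m in zip(batch.pairs, merges):
                    if m.merged:
                        records.append(annotator.annotate(m.seq, pair.read_id,
                                                          chain))
                    else:
                        records.append(AnnotatedRearrangement(
                            read_id=pair.read_id, sequence=pair.seq1,
                            expected_chain=chain, fail_reason="unmerged"))
                survivors, tally = filter_annotations(records,
                                                      config.min_v_identity)
                frame = annotations_to_frame(records, include_sequence=False)
                write_rearrangements(
                    frame, outdir / f"{lib.name}_{chain}_rearrangements.tsv",
                    meta)

                stage = f"count_cdr3[{lib.name},{chain}]"
                table = count_cdr3(survivors, lib.name, chain)
                count_tables[(lib.name, chain)] = table
                write_report_table(table.to_frame(),
                                   outdir / f"{lib.name}_{chain}_cdr3_counts.tsv",
                                   meta)
                profile = charge_distribution(table, scheme)
                profiles[(lib.name, chain)] = profile
                write_report_table(profile.to_frame(),
                                   outdir / f"{lib.name}_{chain}_charge_profile.tsv",
                                   meta)
                manifest["stages"][f"{lib.name}/{chain}"] = {
                    "reads": len(batch.pairs),
                    "merged": int(sum(m.merged for m in merges)),
                    "pass_filter": len(survivors),
                    "excluded": dict(sorted(tally.items())),
                    "unique_cdr3": len(table.counts),
                    "cdr3_reads": table.total,
                }

        baseline_name = config.libraries[0].name
        sublibs = [lib.name for lib in config.libraries[1:]]
        enrichment: dict[tuple[str, str], list[EnrichmentRecord]] = {}
        comparisons: dict[tuple[str, str], ChargeComparison] = {}
        poly: dict[str, object] = {}
        for chain in CHAINS:
            per_lib: dict[str, list[EnrichmentRecord]] = {}
            for sub in sublibs:
                stage = f"enrichment[{sub},{chain}]"
                fit = fit_selection_regression(
                    count_tables[(baseline_name, chain)],
                    count_tables[(sub, chain)], transform=config.transform)
                recs = detect_outliers(fit, alpha=config.alpha)
                enrichment[(sub, chain)] = recs
                per_lib[sub] = recs
                write_report_table(enrichment_frame(recs, chain),
                                   outdir / f"enrichment_{sub}_{chain}.tsv", meta)
                stage = f"charge_comparison[{sub},{chain}]"
                comp = compare_profiles(profiles[(baseline_name, chain)],
                                        profiles[(sub, chain)])
                comparisons[(sub, chain)] = comp
                write_report_table(comp.aggregates,
                                   outdir / f"charge_comparison_{sub}_{chain}.tsv",
                                   meta)
            stage = f"polyreactivity[{chain}]"
            subset = tuple(s for s in ("MBP", "LMP1", "LMP1_MBP") if s in sublibs)
            poly[chain] = polyreactivity_flags(per_lib,
                                               cross_reactive_subset=subset)
            write_report_table(poly[chain],
                               outdir / f"polyreactivity_{chain}.tsv", meta)

        stage = "manifest"
        with open(outdir / "manifest.json", "w", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunReport(config=config, outdir=outdir, manifest=manifest,
                     germline=germline, repertoires=repertoires,
                     planted=planted, count_tables=count_tables,
                     enrichment=enrichment, polyreactivity=poly,
                     charge_profiles=profiles, charge_comparisons=comparisons)
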