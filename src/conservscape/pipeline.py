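"""End-to-end orchestration: one config in, one audited run directory out.

``run_pipeline`` chains the stages — (optionally) simulate, score, region
summaries, dual-alignment fingerprint, clade-stratified motif presence, and
structure painting — writing plain-text TSV outputs plus a ``run.log`` that
records versions, the seed, and every resolved default, so no threshold the
analysis depends on is silent.  Given the same config and seed the TSV
outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .conservation_core import (
    DEFAULT_K,
    SiteScoreTable,
    build_nj_tree,
    default_model,
    score_alignment,
)
from .io_formats import (
    Alignment,
    CladeTable,
    PhyloTree,
    read_alignment,
    read_clade_table,
    read_structure,
    read_tree,
    write_alignment,
    write_clade_table,
    write_structure,
    write_tree,
)
from .motif_scan import DEFAULT_MOTIFS, compile_pattern, anchored_clade_presence
from .refmap import annotate_score_table, build_refmap
from .region_fingerprint import (
    DEFAULT_CONSERVED_GRADES,
    DEFAULT_TAU_CONSERVED,
    DEFAULT_TAU_VARIABLE,
    Region,
    default_regions,
    fingerprint_classify,
    region_conservation_percent,
)
from .seqsim import SimulationConfig, simulate_dataset
from .structure_map import paint_bfactor


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run; round-trips through YAML."""

    out_dir: str
    seed: int = 0
    # data: either an alignment path or a simulation block
    alignment: str | None = None
    simulate: Mapping[str, Any] | None = None
    tree: str | None = None
    clades: str | None = None
    ref_id: str | None = None
    ref_offset: int = 1
    identity_threshold: float | None = None  # curation filter, % identity to ref
    # scoring
    K: int = DEFAULT_K
    alpha: float | str = "estimate"
    # reporting
    regions: Mapping[str, Sequence[Sequence[int]]] | None = None
    motifs: Sequence[Mapping[str, Any]] | None = None
    conserved_grades: tuple[int, ...] = tuple(sorted(DEFAULT_CONSERVED_GRADES))
    tau_c: float = DEFAULT_TAU_CONSERVED
    tau_v: float = DEFAULT_TAU_VARIABLE
    # fingerprint: a second (cross-family) alignment sharing the reference
    cross_alignment: str | None = None
    cross_ref_id: str | None = None
    # structure painting
    structure: str | None = None
    chain: str = "A"
    paint_mode: str = "score"

    def __post_init__(self) -> None:
        if self.alignment is None and self.simulate is None:
            raise ValueError("config needs an alignment path or a simulate block")
        if not 1 <= min(self.conserved_grades) and max(self.conserved_grades) <= 9:
            raise ValueError("conserved_grades must be within 1..9")
        if self.tau_v < self.tau_c:
            raise ValueError("tau_v must be >= tau_c")
        if self.identity_threshold is not None and not (
            0 <= self.identity_threshold <= 100
        ):
            raise ValueError("identity_threshold must be in [0, 100]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml_text(self) -> str:
        data = {k: v for k, v in self.__dict__.items()}
        data["simulate"] = dict(self.simulate) if self.simulate else None
        data["regions"] = (
            {k: [list(iv) for iv in v] for k, v in self.regions.items()}
            if self.regions
            else None
        )
        data["motifs"] = [dict(m) for m in self.motifs] if self.motifs else None
        data["conserved_grades"] = list(self.conserved_grades)
        return yaml.safe_dump(data, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        data = yaml.safe_load(self.to_yaml_text())
        data.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(data, sort_keys=True).encode()).hexdigest()[:12]


def _resolved_regions(config: RunConfig) -> tuple[Region, ...]:
    if config.regions is None:
        return default_regions()
    return tuple(
        Region(name, tuple((int(s), int(e)) for s, e in ivs))
        for name, ivs in config.regions.items()
    )


def _resolved_motifs(config: RunConfig) -> list[tuple[str, str, tuple[int, int] | None]]:
    if config.motifs is None:
        return [(name, text, None) for name, text in DEFAULT_MOTIFS]
    out = []
    for m in config.motifs:
        window = tuple(m["window"]) if m.get("window") else None
        out.append((m["name"], m["pattern"], window))
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute every applicable stage; returns the run directory.

    Stages whose inputs are absent (no clade table -> motif presence, no
    cross alignment -> fingerprint, no structure -> painting) are skipped
    with the reason recorded in ``run.log``; any stage failure aborts with
    the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"conservscape {__version__} (python {sys.version.split()[0]})",
        f"config hash {config.config_hash()}",
        f"seed {config.seed}",
        f"substitution model {default_model().name}; K={config.K}; alpha={config.alpha}",
        f"conserved grades {sorted(config.conserved_grades)}; "
        f"tau_c={config.tau_c}; tau_v={config.tau_v}",
        f"reference offset {config.ref_offset}",
    ]
    header = [f"conservscape {__version__}", f"config {config.config_hash()}"]

    # --- stage: data ------------------------------------------------------
    stage = "data"
    try:
        clade_table: CladeTable | None = None
        tree: PhyloTree | None = None
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            if "site_blocks" in sim and sim["site_blocks"] is not None:
                sim["site_blocks"] = tuple(
                    (int(n), float(r)) for n, r in sim["site_blocks"]
                )
            sim_config = SimulationConfig(**sim)
            alignment, tree, clade_table, _truth = simulate_dataset(sim_config)
            write_alignment(alignment, str(out / "simulated.fasta"))
            write_tree(tree, str(out / "simulated.nwk"))
            write_clade_table(clade_table, str(out / "simulated_clades.tsv"))
            log.append(f"simulated dataset: {sim_config}")
        else:
            alignment = read_alignment(config.alignment)
            log.append(f"alignment {config.alignment}: {alignment.n_seqs} x {alignment.n_cols}")
        if config.tree:
            tree = read_tree(config.tree)
            log.append(f"tree {config.tree}")
        if config.clades:
            clade_table = read_clade_table(config.clades)
            clade_table.validate_against(alignment)
            log.append(f"clade table {config.clades}")
        ref_id = config.ref_id or alignment.ids[0]
        if config.ref_id is None:
            log.append(f"reference id defaulted to first record {ref_id!r}")
        if config.identity_threshold is not None:
            from .region_fingerprint import filter_by_identity

            before = alignment.n_seqs
            alignment = filter_by_identity(alignment, ref_id, config.identity_threshold)
            log.append(
                f"identity filter >= {config.identity_threshold}% to {ref_id}: "
                f"{before} -> {alignment.n_seqs} sequences"
            )
            if tree is not None and set(tree.leaf_labels) != set(alignment.ids):
                tree = None
                log.append("provided tree dropped after identity filter; rebuilding by NJ")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: scoring ---------------------------------------------------
    stage = "scoring"
    try:
        if tree is None:
            tree = build_nj_tree(alignment)
            log.append("guide tree: neighbor joining on Kimura-corrected distances")
        score_table = score_alignment(
            alignment, tree=tree, K=config.K, alpha=config.alpha
        )
        refmap = build_refmap(alignment, ref_id, config.ref_offset)
        annotate_score_table(score_table, refmap)
        score_table.write_tsv(str(out / "scores.tsv"), header_lines=header)
        log.append(f"scored {alignment.n_cols} columns; reference {ref_id}")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: regions ---------------------------------------------------
    stage = "regions"
    try:
        grades = frozenset(config.conserved_grades)
        rows = []
        for region in _resolved_regions(config):
            try:
                rep = region_conservation_percent(score_table, refmap, region, grades)
            except ValueError as exc:
                log.append(f"region {region.name!r} skipped: {exc}")
                continue
            rows.append(rep)
        with open(out / "regions.tsv", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("region\tpercent_conserved\tn_conserved\tn_mapped\tunmapped\n")
            for rep in rows:
                unm = ",".join(map(str, rep.unmapped_residues))
                fh.write(
                    f"{rep.name}\t{rep.percent_conserved:.1f}\t{rep.n_conserved}\t"
                    f"{rep.n_mapped}\t{unm}\n"
                )
        log.append(f"regions: {len(rows)} reported")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: fingerprint ----------------------------------------------
    stage = "fingerprint"
    try:
        if config.cross_alignment is None:
            log.append("fingerprint skipped: no cross-family alignment provided")
        else:
            cross_aln = read_alignment(config.cross_alignment)
            cross_ref = config.cross_ref_id or ref_id
            cross_scores = score_alignment(cross_aln, K=config.K, alpha=config.alpha)
            cross_map = build_refmap(cross_aln, cross_ref, config.ref_offset)
            annotate_score_table(cross_scores, cross_map)
            calls, uncomparable = fingerprint_classify(
                score_table.score_by_residue(),
                cross_scores.score_by_residue(),
                config.tau_c,
                config.tau_v,
            )
            with open(out / "fingerprint.tsv", "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                fh.write("ref_residue\ts_within\ts_cross\tlabel\n")
                for c in calls:
                    fh.write(
                        f"{c.ref_residue}\t{c.s_within:.6f}\t{c.s_cross:.6f}\t{c.label}\n"
                    )
            log.append(
                f"fingerprint: {len(calls)} positions classified, "
                f"{len(uncomparable)} uncomparable"
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: motifs ----------------------------------------------------
    stage = "motifs"
    try:
        if clade_table is None:
            log.append("motif stage skipped: no clade table provided")
        else:
            with open(out / "motifs.tsv", "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                fh.write("motif\tclade\tn\tfraction\n")
                for name, text, window in _resolved_motifs(config):
                    pattern = compile_pattern(text, name=name)
                    if window is None:
                        window = (
                            min(refmap.res_to_col),
                            max(refmap.res_to_col),
                        )
                        log.append(
                            f"motif {name!r}: no window given, scanning full "
                            f"reference span {window[0]}-{window[1]}"
                        )
                    presence = anchored_clade_presence(
                        alignment, clade_table, refmap, pattern, window
                    )
                    for clade, (frac, n) in presence.items():
                        fh.write(f"{name}\t{clade}\t{n}\t{frac:.4f}\n")
            log.append("motif presence written")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: paint -----------------------------------------------------
    stage = "paint"
    try:
        if config.structure is None:
            log.append("painting skipped: no structure provided")
        else:
            structure = read_structure(config.structure)
            report = paint_bfactor(
                structure, score_table, refmap, config.chain, config.paint_mode
            )
            write_structure(report.painted, str(out / "painted.pdb"))
            log.append(
                f"painted chain {config.chain} ({config.paint_mode}): "
                f"{len(report.mapped_residues)} mapped, "
                f"{len(report.unmapped_residues)} unmapped residues"
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / "run_config.yaml").write_text(config.to_yaml_text())
    return out
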