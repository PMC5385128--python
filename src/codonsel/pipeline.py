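"""End-to-end per-gene workflow: back-translation, column policy, M0 fit,
the requested selection analyses, and TSV/Newick report output.

All randomness flows from the config seed; two runs with identical configs
produce byte-identical reports (logs carry wall-clock timings and are the
one non-deterministic output)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .likelihood import fit, map_ancestral_codons
from .seqio import (
    back_translate,
    drop_unusable_columns,
    read_codon_alignment,
    read_coding_fasta,
    read_fasta,
    read_protein_alignment,
    write_codon_alignment,
)
from .selection import (
    branch_site_test,
    clade_model_test,
    free_ratio,
    results_table,
    sitewise_omega,
)
from .spectral import genotype_table
from .tree import parse_newick

KNOWN_ANALYSES = (
    "free-ratio",
    "branch-site",
    "clade-model",
    "sitewise",
    "ancestral",
)


@dataclass
class RunConfig:
    """Declarative configuration for one gene analysis."""

    tree: str  # Newick path ('#1' labels mark foreground)
    out_dir: str
    gene: str = "gene"
    # either a ready codon alignment...
    codon_alignment: str | None = None
    # ...or a CDS FASTA plus protein guide alignment to back-translate
    cds: str | None = None
    protein_alignment: str | None = None
    analyses: list[str] = field(default_factory=lambda: ["clade-model"])
    foreground: list[str] = field(default_factory=list)
    column_policy: str = "all-gap"
    freq_scheme: str = "F3x4"
    alpha: float = 0.05
    posterior_threshold: float = 0.75
    posterior_mode: str = "neb"
    restarts: int = 2
    seed: int = 0
    ancestral_node: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.posterior_threshold < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        paths = [self.tree, self.codon_alignment, self.cds, self.protein_alignment]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.codon_alignment is None and (
            self.cds is None or self.protein_alignment is None
        ):
            raise ValueError(
                "provide codon_alignment, or cds plus protein_alignment"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data.pop("config_version", 1) != 1:
            raise ValueError("unsupported config schema version")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_gene(config: RunConfig) -> dict:
    """Execute the configured analyses; returns a report-bundle dict of
    output paths. Any stage failure is logged with its stage name and
    re-raised."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"codonsel {__version__}",
        f"config_hash {config.digest()}",
    ]
    bundle: dict[str, str] = {}
    t_start = time.perf_counter()

    def stage(name):
        log_lines.append(
            f"stage {name} at {time.perf_counter() - t_start:.2f}s"
        )

    try:
        stage("inputs")
        tree = parse_newick(Path(config.tree).read_text())
        if config.foreground:
            tree.set_foreground(config.foreground)
        if config.codon_alignment:
            aln = read_codon_alignment(config.codon_alignment)
        else:
            guide = read_protein_alignment(config.protein_alignment)
            cds = read_coding_fasta(config.cds)
            aln = back_translate(guide, cds)
        aln, provenance = drop_unusable_columns(aln, config.column_policy)
        aln_path = out / f"{config.gene}.codon.fasta"
        write_codon_alignment(aln_path, aln)
        bundle["alignment"] = str(aln_path)

        stage("m0")
        m0 = fit(
            aln, tree, "M0",
            freq_scheme=config.freq_scheme, restarts=1, seed=config.seed,
        )
        (out / f"{config.gene}.M0.txt").write_text(m0.to_report())
        bundle["m0"] = str(out / f"{config.gene}.M0.txt")

        test_results = []
        common = dict(
            gene=config.gene,
            alpha=config.alpha,
            restarts=config.restarts,
            seed=config.seed,
            m0_fit=m0,
            freq_scheme=config.freq_scheme,
        )
        if "free-ratio" in config.analyses:
            stage("free-ratio")
            rates, _ = free_ratio(
                aln, tree, restarts=config.restarts, seed=config.seed,
                m0_fit=m0, freq_scheme=config.freq_scheme,
            )
            import pandas as pd

            path = out / f"{config.gene}.free_ratio.tsv"
            pd.DataFrame([r.to_row() for r in rates]).to_csv(
                path, sep="\t", index=False, float_format="%.6g"
            )
            bundle["free_ratio"] = str(path)
            # per-branch omegas as Newick comments
            annotated = m0.tree.copy()
            for v, r in zip(annotated.branch_nodes(), rates):
                annotated.nodes[v].name = (
                    annotated.nodes[v].name + f"[omega={r.omega:.4g}]"
                    if not annotated.nodes[v].children
                    else f"[omega={r.omega:.4g}]"
                )
            (out / f"{config.gene}.free_ratio.nwk").write_text(
                annotated.to_newick() + "\n"
            )
            bundle["free_ratio_tree"] = str(out / f"{config.gene}.free_ratio.nwk")
        if "branch-site" in config.analyses:
            stage("branch-site")
            res, post = branch_site_test(
                aln, tree,
                posterior_mode=config.posterior_mode,
                posterior_threshold=config.posterior_threshold,
                **common,
            )
            test_results.append(res)
            path = out / f"{config.gene}.branch_site.sites.tsv"
            post.to_frame().to_csv(
                path, sep="\t", index=False, float_format="%.6g"
            )
            bundle["branch_site_sites"] = str(path)
        if "clade-model" in config.analyses:
            stage("clade-model")
            res, post = clade_model_test(
                aln, tree,
                posterior_mode=config.posterior_mode,
                posterior_threshold=config.posterior_threshold,
                **common,
            )
            test_results.append(res)
            path = out / f"{config.gene}.clade_model.sites.tsv"
            post.to_frame().to_csv(
                path, sep="\t", index=False, float_format="%.6g"
            )
            bundle["clade_model_sites"] = str(path)
        if test_results:
            path = out / f"{config.gene}.tests.tsv"
            results_table(test_results).to_csv(
                path, sep="\t", index=False, float_format="%.6g"
            )
            bundle["tests"] = str(path)
        if "sitewise" in config.analyses:
            stage("sitewise")
            df = sitewise_omega(aln, tree, m0_fit=m0, seed=config.seed)
            path = out / f"{config.gene}.sitewise_omega.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            bundle["sitewise"] = str(path)
        if "ancestral" in config.analyses:
            stage("ancestral")
            node = config.ancestral_node or m0.tree.nodes[m0.tree.root].index
            rows = map_ancestral_codons(m0, node)
            path = out / f"{config.gene}.ancestral.tsv"
            with open(path, "w") as fh:
                fh.write("site\tcodon\tamino_acid\tposterior\n")
                for s, (codon, aa, p) in enumerate(rows, start=1):
                    fh.write(f"{s}\t{codon}\t{aa}\t{p:.6g}\n")
            bundle["ancestral"] = str(path)
    except Exception as exc:
        log_lines.append(f"FAILED: {type(exc).__name__}: {exc}")
        (out / f"{config.gene}.log").write_text("\n".join(log_lines) + "\n")
        raise
    stage("done")
    (out / f"{config.gene}.log").write_text("\n".join(log_lines) + "\n")
    bundle["log"] = str(out / f"{config.gene}.log")
    return bundle


def run_spectral(
    panel_fasta, out_path, reference=None, experimental: dict | None = None
) -> "pd.DataFrame":
    """Genotype/lambda_max table for a FASTA panel of L-opsin proteins."""
    import pandas as pd  # noqa: F401  (re-exported type in docstring)

    panel = read_fasta(panel_fasta)
    df = genotype_table(panel, reference=reference, experimental=experimental)
    df.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return df
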