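"""One-command orchestration: FASTA in, all per-gene and cohort tables out.

The per-gene table joins every gene-level statistic (entropy profile, 24 skew
cells, RSCU bias-class counts, ENC/GC3 with the null-curve residual, PR2
coordinates); cohort-level attachments are the Vs dispersion table, the
absent-codon report, the 18-cell skew correlation table and PCA of both
usage spaces. All tables are written as TSV with missing values encoded
"NA", in input order, so reruns on identical input produce identical bytes.
Genes that fail a stage are reported in a skipped-genes table, never dropped
silently: analyzed + skipped = input records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codon_metrics import (
    absent_codon_report,
    enc,
    gc3,
    rscu,
    vs_dispersion,
)
from .composition import (
    SCOPES,
    SKEW_TYPES,
    entropy_profile,
    nucleotide_composition,
    skew_profile,
)
from .diagnostics import pca_usage, pr2_point, rscu_matrix, skew_correlation_table
from .genetic_code import NUCLEOTIDES, standard_code
from .sequence_io import (
    amino_acid_frequencies,
    count_codons,
    read_cds_fasta,
    validate_cds,
)

logger = logging.getLogger(__name__)

_SKEW_COLS = [
    f"{t}_skew" if scope == "overall" else f"{t}_skew_{scope}"
    for t in SKEW_TYPES
    for scope in SCOPES
]


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str
    output_dir: str
    strictness: str = "lenient"
    rscu_over: float = 1.6
    rscu_under: float = 0.6
    enc_sig: float = 35.0
    pca_components: int = 2
    plots: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.rscu_under < self.rscu_over):
            raise ValueError("need 0 < rscu_under < rscu_over")
        if self.enc_sig <= 0:
            raise ValueError("enc_sig must be positive")


@dataclass
class CohortResultTable:
    """In-memory result bundle mirroring the files run_analyze writes."""

    per_gene: pd.DataFrame
    vs_table: pd.DataFrame
    rscu_values: pd.DataFrame
    absent_codons: pd.DataFrame
    skew_correlations: pd.DataFrame
    pca_rscu: object | None
    pca_aa: object | None
    skipped: pd.DataFrame
    validation: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index, float_format="%.6f")


def run_analyze(config: PipelineConfig) -> CohortResultTable:
    """Execute the full pipeline and write every output table.

    Per-gene failures (for example a gene with no sense codons) are logged
    and collected in ``skipped_genes.tsv`` without aborting the cohort.
    """
    t0 = time.monotonic()
    code = standard_code()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = read_cds_fasta(config.input_path, strictness=config.strictness)  # type: ignore[arg-type]
    logger.info("read %d coding sequences from %s", len(seqs), config.input_path)

    validation_rows = []
    gene_rows = []
    skipped_rows = []
    rscu_by_gene: list[tuple[str, dict]] = []
    rscu_vectors = []
    aa_rows = []
    skew_profiles = []
    analyzed_ids = []

    for seq in seqs:
        report = validate_cds(seq, code)
        validation_rows.append(
            {
                "id": seq.id,
                "ok": report.ok,
                "issue_codes": ";".join(report.codes) if report.codes else "",
            }
        )
        try:
            comp = nucleotide_composition(seq)
            ent = entropy_profile(comp)
            skews = skew_profile(comp)
            counts = count_codons(seq)
            vec = rscu(counts, code)
            classes = _class_counts(vec, config)
            aa_freq = amino_acid_frequencies(counts, code)
            p = pr2_point(counts, code)
            row = {
                "id": seq.id,
                "species": seq.species,
                "length_nt": len(seq),
                "n_codons": len(seq.codons),
                "H_overall": ent.H_overall,
                "H1": ent.H_pos1,
                "H2": ent.H_pos2,
                "H3": ent.H_pos3,
            }
            for n in NUCLEOTIDES:
                row[f"H_{n}"] = ent.per_nucleotide[n]
            for t in SKEW_TYPES:
                for scope in SCOPES:
                    col = f"{t}_skew" if scope == "overall" else f"{t}_skew_{scope}"
                    row[col] = skews.get(t, scope)
            row.update(classes)
            try:
                e = enc(counts, code)
                row.update(
                    enc=e.enc,
                    gc3=e.gc3,
                    expected_enc=e.expected_enc,
                    enc_minus_expected=e.residual,
                    significant_bias=e.enc < config.enc_sig,
                )
            except ValueError as exc:
                logger.warning("gene %s: ENC not estimable (%s)", seq.id, exc)
                row.update(
                    enc=math.nan,
                    gc3=_safe_gc3(counts, code),
                    expected_enc=math.nan,
                    enc_minus_expected=math.nan,
                    significant_bias=None,
                )
            row["pr2_at_bias"] = p.at_bias
            row["pr2_gc_bias"] = p.gc_bias
            gene_rows.append(row)
            rscu_by_gene.append((seq.id, vec.values))
            rscu_vectors.append((seq.species, vec))
            aa_rows.append({"id": seq.id, **aa_freq})
            skew_profiles.append(skews)
            analyzed_ids.append(seq.id)
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", seq.id, exc)
            skipped_rows.append({"id": seq.id, "reason": str(exc)})

    per_gene = pd.DataFrame(gene_rows)
    validation = pd.DataFrame(validation_rows)
    skipped = pd.DataFrame(skipped_rows, columns=["id", "reason"])

    rscu_mat = rscu_matrix(rscu_by_gene, code) if rscu_by_gene else pd.DataFrame()
    vs_table = vs_dispersion(rscu_mat, code) if len(rscu_mat) else pd.DataFrame()
    absent = absent_codon_report(rscu_vectors, code)
    correlations = (
        skew_correlation_table(skew_profiles) if len(skew_profiles) >= 3 else pd.DataFrame()
    )

    pca_rscu = pca_aa = None
    if len(rscu_mat) >= 2:
        aa_mat = pd.DataFrame(aa_rows).set_index("id")
        for name, mat in (("rscu59", rscu_mat), ("aa20", aa_mat)):
            if float(mat.var(axis=0, skipna=True).sum()) == 0.0:
                logger.warning("%s PCA skipped: matrix has zero variance", name)
                continue
            try:
                result = pca_usage(mat, name, config.pca_components)  # type: ignore[arg-type]
            except ValueError as exc:
                logger.warning("%s PCA skipped: %s", name, exc)
                continue
            if name == "rscu59":
                pca_rscu = result
            else:
                pca_aa = result

    _write_tsv(per_gene, out_dir / "per_gene.tsv")
    _write_tsv(validation, out_dir / "validation.tsv")
    _write_tsv(skipped, out_dir / "skipped_genes.tsv")
    _write_tsv(vs_table, out_dir / "vs.tsv")
    _write_tsv(
        rscu_mat.reset_index(names="id") if len(rscu_mat) else rscu_mat,
        out_dir / "rscu_matrix.tsv",
    )
    _write_tsv(absent, out_dir / "absent_codons.tsv")
    _write_tsv(correlations, out_dir / "skew_correlations.tsv")
    if len(per_gene):
        _write_tsv(
            per_gene[
                ["id", "gc3", "enc", "expected_enc", "enc_minus_expected", "significant_bias"]
            ],
            out_dir / "enc_gc3.tsv",
        )
        _write_tsv(per_gene[["id", "pr2_at_bias", "pr2_gc_bias"]], out_dir / "pr2.tsv")
    for result, stem in ((pca_rscu, "pca_rscu"), (pca_aa, "pca_aa")):
        if result is not None:
            _write_tsv(
                result.coordinates.reset_index(names="id"), out_dir / f"{stem}_coords.tsv"
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "component": result.coordinates.columns,
                        "explained_variance_ratio": result.explained_variance_ratio,
                    }
                ),
                out_dir / f"{stem}_variance.tsv",
            )
    if config.plots:
        _write_plots(per_gene, pca_rscu, out_dir)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": _sha256(config.input_path),
        "n_input": len(seqs),
        "n_analyzed": len(analyzed_ids),
        "n_skipped": len(skipped),
        "elapsed_s": round(time.monotonic() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info(
        "analyzed %d/%d genes in %.2fs", len(analyzed_ids), len(seqs), manifest["elapsed_s"]
    )
    return CohortResultTable(
        per_gene=per_gene,
        vs_table=vs_table,
        rscu_values=rscu_mat,
        absent_codons=absent,
        skew_correlations=correlations,
        pca_rscu=pca_rscu,
        pca_aa=pca_aa,
        skipped=skipped,
        validation=validation,
        manifest=manifest,
    )


def _class_counts(vec, config: PipelineConfig) -> dict[str, int]:
    over = under = absent = undefined = 0
    for codon, v in vec.values.items():
        if math.isnan(v):
            undefined += 1
        elif v == 0:
            absent += 1
        elif v > config.rscu_over:
            over += 1
        elif v < config.rscu_under:
            under += 1
    return {
        "n_overrepresented": over,
        "n_underrepresented": under,
        "n_absent_codons": absent,
        "n_undefined_codons": undefined,
    }


def _safe_gc3(counts, code) -> float:
    try:
        return gc3(counts, code)
    except ValueError:
        return math.nan


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_plots(per_gene: pd.DataFrame, pca_rscu, out_dir: Path) -> None:
    # cosmetic output only; never load-bearing
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(per_gene):
        fig, ax = plt.subplots(figsize=(5, 4))
        s = np.linspace(0.0, 1.0, 200)
        ax.plot(s, 2 + s + 29 / (s**2 + (1 - s) ** 2), "k-", lw=1, label="expected")
        ax.scatter(per_gene["gc3"], per_gene["enc"], s=12, alpha=0.7)
        ax.set_xlabel("GC3")
        ax.set_ylabel("ENC")
        ax.legend()
        fig.savefig(out_dir / "enc_gc3.png", dpi=150, bbox_inches="tight")
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(per_gene["pr2_gc_bias"], per_gene["pr2_at_bias"], s=12, alpha=0.7)
        ax.axhline(0.5, color="grey", lw=0.8)
        ax.axvline(0.5, color="grey", lw=0.8)
        ax.set_xlabel("GC bias G3/(G3+C3)")
        ax.set_ylabel("AT bias A3/(A3+T3)")
        fig.savefig(out_dir / "pr2.png", dpi=150, bbox_inches="tight")
        plt.close(fig)

    if pca_rscu is not None and pca_rscu.coordinates.shape[1] >= 2:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(
            pca_rscu.coordinates.iloc[:, 0], pca_rscu.coordinates.iloc[:, 1], s=12, alpha=0.7
        )
        evr = pca_rscu.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
        ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
        fig.savefig(out_dir / "pca_rscu.png", dpi=150, bbox_inches="tight")
        plt.close(fig)


def summarize(results: CohortResultTable) -> str:
    """Plain-text cohort summary: medians/IQRs, bias counts, Tukey outliers."""
    pg = results.per_gene
    if not len(pg):
        raise ValueError("empty results")
    lines = [f"Cohort of {len(pg)} genes ({len(results.skipped)} skipped)"]
    for col, label in (
        ("H_overall", "entropy H (bits)"),
        ("enc", "ENC"),
        ("gc3", "GC3"),
    ):
        vals = pg[col].dropna()
        if not len(vals):
            continue
        q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = pg.loc[(pg[col] < lo) | (pg[col] > hi), "species"].tolist()
        lines.append(
            f"  {label}: median {med:.4f}  IQR [{q1:.4f}, {q3:.4f}]  "
            f"outliers (1.5*IQR): {len(outliers)}"
        )
        if outliers:
            lines.append(f"    {', '.join(map(str, outliers[:10]))}")
    n_sig = int(pg["significant_bias"].eq(True).sum())
    lines.append(f"  genes with significant codon bias (ENC < 35): {n_sig}")
    n_absent_events = (
        int(results.absent_codons["n_species"].sum()) if len(results.absent_codons) else 0
    )
    lines.append(
        f"  absent-codon events: {n_absent_events} across "
        f"{len(results.absent_codons)} codons"
    )
    return "\n".join(lines)
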