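"""Readers, writers and run manifests.

Coordinates are 1-based in VCF/TSV interfaces and 0-based half-open in the
BED output. The posterior JSON schema embeds variant and trait names so a
fitted model round-trips through a single file.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    GenotypePanel,
    LDMatrix,
    MissingGenotype,
    ParseError,
    SchemaError,
    SummaryStatSet,
    TraitMatrix,
    VariationalPosterior,
)

POSTERIOR_SCHEMA = "cafeh-posterior-1"

SUMMARY_COLUMNS = [
    "study",
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "n",
]


# ---------------------------------------------------------------------------
# genotypes


def _read_matrix_genotypes(path: Path) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ParseError(f"{path}: empty header line")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: no genotype rows")
    return GenotypePanel(genotypes=np.array(rows), variant_ids=header)


def _read_vcf_genotypes(path: Path) -> GenotypePanel:
    import pysam

    ids, chrom, pos, ref, alt, cols = [], [], [], [], [], []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            dosages = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    raise MissingGenotype(
                        f"{path}: uncalled genotype at {rec.chrom}:{rec.pos} "
                        f"sample {s}"
                    )
                dosages.append(float(sum(1 for a in gt if a == 1)))
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chrom.append(str(rec.chrom))
            pos.append(int(rec.pos))
            ref.append(str(rec.ref))
            alt.append(str(alts[0]))
            cols.append(dosages)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s)", stacklevel=2)
    if not cols:
        raise ParseError(f"{path}: no usable biallelic records")
    return GenotypePanel(
        genotypes=np.array(cols).T,
        variant_ids=ids,
        chrom=np.array(chrom),
        pos=np.array(pos, int),
        ref=np.array(ref),
        alt=np.array(alt),
    )


def read_genotypes(path, format: str = "auto") -> GenotypePanel:
    """Read genotypes from a header+matrix text file or a VCF.

    VCF GT fields become dosages (phased and unphased identically);
    multiallelic records are skipped with a counted warning.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".bcf"} or str(path).endswith(
            ".vcf.gz"
        ) else "matrix"
    if format == "vcf":
        return _read_vcf_genotypes(path)
    if format == "matrix":
        return _read_matrix_genotypes(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.genotypes, columns=panel.variant_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# traits


def read_traits(path) -> TraitMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no trait columns")
    return TraitMatrix(df.to_numpy(float), list(df.columns))


def write_traits(traits: TraitMatrix, path) -> None:
    pd.DataFrame(traits.values, columns=traits.trait_names).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# summary statistics and LD


def read_summary_stats(path, z: bool = False) -> list[SummaryStatSet]:
    """Read long-form per-study summary statistics (one set per study).

    With ``z=True`` the ``beta`` column is interpreted as a z-score and
    converted via se = 1/sqrt(n), beta = z * se.
    """
    df = pd.read_csv(path, sep="\t")
    cols = SUMMARY_COLUMNS if not z else [c for c in SUMMARY_COLUMNS if c != "se"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    if z:
        df = df.copy()
        df["se"] = 1.0 / np.sqrt(df["n"].astype(float))
        df["beta"] = df["beta"].astype(float) * df["se"]
    if (df["se"] <= 0).any():
        raise SchemaError(f"{path}: non-positive standard error")
    out = []
    for study, sub in df.groupby("study", sort=False):
        out.append(
            SummaryStatSet(
                beta=sub["beta"].to_numpy(float)[None, :],
                se=sub["se"].to_numpy(float)[None, :],
                n=np.array([float(sub["n"].iloc[0])]),
                variant_ids=list(sub["variant_id"].astype(str)),
                study_names=[str(study)],
                chrom=sub["chrom"].astype(str).to_numpy(),
                pos=sub["pos"].to_numpy(int),
                effect_allele=sub["effect_allele"].astype(str).to_numpy(),
                other_allele=sub["other_allele"].astype(str).to_numpy(),
            )
        )
    return out


def write_summary_stats(stats: SummaryStatSet, path) -> None:
    rows = []
    for t, study in enumerate(stats.study_names):
        for g, vid in enumerate(stats.variant_ids):
            rows.append(
                {
                    "study": study,
                    "variant_id": vid,
                    "chrom": stats.chrom[g],
                    "pos": int(stats.pos[g]),
                    "effect_allele": stats.effect_allele[g],
                    "other_allele": stats.other_allele[g],
                    "beta": stats.beta[t, g],
                    "se": stats.se[t, g],
                    "n": stats.n[t],
                }
            )
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ld(path, variants_path) -> LDMatrix:
    """Whitespace-delimited square LD matrix plus an order-matched variant list."""
    r = np.loadtxt(path, ndmin=2)
    variant_ids = [ln.strip() for ln in open(variants_path) if ln.strip()]
    if r.shape[0] != len(variant_ids):
        raise SchemaError(
            f"LD dimension {r.shape[0]} does not match {len(variant_ids)} variants"
        )
    d = np.diag(r)
    if np.max(np.abs(d - 1.0)) > 1e-8:
        if np.any(d <= 0):
            raise SchemaError("LD diagonal has non-positive entries")
        warnings.warn("LD diagonal differs from 1; renormalizing", stacklevel=2)
        s = np.sqrt(d)
        r = r / np.outer(s, s)
        np.fill_diagonal(r, 1.0)
    return LDMatrix(r=0.5 * (r + r.T), variant_ids=variant_ids)


def write_ld(ld: LDMatrix, path, variants_path) -> None:
    np.savetxt(path, ld.r, fmt="%.8g")
    Path(variants_path).write_text("\n".join(ld.variant_ids) + "\n")


# ---------------------------------------------------------------------------
# posterior serialization


def posterior_to_dict(
    post: VariationalPosterior,
    variant_ids=None,
    trait_names=None,
    chrom=None,
    pos=None,
) -> dict:
    return {
        "schema": POSTERIOR_SCHEMA,
        "phi": post.phi.tolist(),
        "s_prob": post.s_prob.tolist(),
        "w_mean": post.w_mean.tolist(),
        "w_var": post.w_var.tolist(),
        "alpha_shape": post.alpha_shape.tolist(),
        "alpha_rate": post.alpha_rate.tolist(),
        "tau_shape": post.tau_shape.tolist(),
        "tau_rate": post.tau_rate.tolist(),
        "elbo_trace": list(map(float, post.elbo_trace)),
        "variant_ids": list(variant_ids) if variant_ids is not None else None,
        "trait_names": list(trait_names) if trait_names is not None else None,
        "chrom": [str(c) for c in chrom] if chrom is not None else None,
        "pos": [int(p) for p in pos] if pos is not None else None,
    }


def posterior_from_dict(d: dict) -> tuple[VariationalPosterior, dict]:
    if d.get("schema") != POSTERIOR_SCHEMA:
        raise SchemaError(f"unknown posterior schema {d.get('schema')!r}")
    post = VariationalPosterior(
        phi=np.array(d["phi"]),
        s_prob=np.array(d["s_prob"]),
        w_mean=np.array(d["w_mean"]),
        w_var=np.array(d["w_var"]),
        alpha_shape=np.array(d["alpha_shape"]),
        alpha_rate=np.array(d["alpha_rate"]),
        tau_shape=np.array(d["tau_shape"]),
        tau_rate=np.array(d["tau_rate"]),
        elbo_trace=list(d["elbo_trace"]),
    )
    meta = {k: d.get(k) for k in ("variant_ids", "trait_names", "chrom", "pos")}
    return post, meta


def save_posterior(post, path, **meta) -> None:
    Path(path).write_text(json.dumps(posterior_to_dict(post, **meta)))


def load_posterior(path) -> tuple[VariationalPosterior, dict]:
    return posterior_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# result writers


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    post: VariationalPosterior,
    outdir,
    variant_ids: list[str],
    trait_names: list[str],
    chrom=None,
    pos=None,
    threshold: float = 0.5,
    level: float = 0.95,
    config: dict | None = None,
    seed: int | None = None,
    input_files: list | None = None,
) -> dict:
    """Write components.tsv, credible_sets.bed, coloc_pairs.tsv,
    posterior.json and manifest.json into ``outdir``."""
    from . import __version__
    from .report import coloc_table, components_table, credible_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if chrom is None:
        chrom = ["1"] * len(variant_ids)
    if pos is None:
        pos = list(range(1, len(variant_ids) + 1))

    comp = components_table(post, variant_ids, trait_names, threshold, level)
    comp.to_csv(outdir / "components.tsv", sep="\t", index=False)

    bed_rows = []
    for k in range(post.K):
        if not np.any(post.s_prob[:, k] >= threshold):
            continue
        for g in credible_set(post, k, level):
            bed_rows.append(
                {
                    "chrom": chrom[g],
                    "start": int(pos[g]) - 1,
                    "end": int(pos[g]),
                    "variant": variant_ids[g],
                    "component": k,
                    "mass": float(post.phi[k, g]),
                }
            )
    pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "variant", "component", "mass"]
    ).to_csv(outdir / "credible_sets.bed", sep="\t", index=False, header=True)

    coloc_table(post, trait_names, threshold).to_csv(
        outdir / "coloc_pairs.tsv", sep="\t", index=False
    )

    save_posterior(
        post,
        outdir / "posterior.json",
        variant_ids=variant_ids,
        trait_names=trait_names,
        chrom=chrom,
        pos=pos,
    )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "threshold": threshold,
        "level": level,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            str(p): file_sha256(p) for p in (input_files or []) if Path(p).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
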