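"""Readers and writers: count-matrix TSVs, raw-call tables, fit directories.

All tabular output is UTF-8 TSV with a header row; result tables written by
the CLI carry a ``#``-prefixed provenance header (package version, seed,
config) and are read back with ``comment="#"``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CategorySpace, CountMatrix, SampleSignatureProbs, SignatureSet
from .encoding import SnvCall, SvCall
from .models import ModelConfig, MmctmFit
from .models.fitting import GaussianPrior

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_signatures",
    "read_snv_vcf",
    "read_sv_table",
    "save_fit",
    "load_fit",
]


def write_count_matrix(cm: CountMatrix, path, header_lines: list[str] | None = None
                       ) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        cm.to_frame().to_csv(fh, sep="\t")


def read_count_matrix(path, modality: str | None = None, encoding: str = "full",
                      feature_arity: tuple[int, ...] = ()) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    if modality is None:
        modality = "SV" if any(":" in c for c in df.columns) else "SNV"
    if encoding == "full" and modality == "SNV" and not any("[" in c for c in df.columns):
        # 14-column independent layout round-trips as such
        if df.shape[1] == 14:
            encoding, feature_arity = "independent", (6, 4, 4)
    return CountMatrix.from_frame(df, modality=modality, encoding=encoding,
                                  feature_arity=feature_arity)


def read_signatures(path, modality: str = "SNV", encoding: str = "full",
                    feature_arity: tuple[int, ...] = ()) -> SignatureSet:
    """Load a signature TSV (rows = signatures, columns = category labels).

    Lets published reference signatures drive the simulator in place of
    the bundled synthetic ones.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    space = CategorySpace(modality, tuple(df.columns), encoding, feature_arity)
    return SignatureSet(space, df.to_numpy(), names=list(df.index.astype(str)))


def read_snv_vcf(path, sample_id: str | None = None) -> list[SnvCall]:
    """Read SNV calls from a VCF.

    For multi-sample VCFs each variant is attributed to every sample
    carrying a non-reference genotype; for sample-less (or site-only) VCFs
    a ``sample_id`` must name the single sample the file belongs to.
    Indels and multi-allelic records are passed through and later skipped
    (with logging) by the encoder.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples and sample_id is None:
        raise ValueError(f"{path}: VCF has no sample columns; pass sample_id")
    calls: list[SnvCall] = []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else ""
        if samples:
            carriers = [s for s, g in zip(samples, var.gt_types) if g in (1, 3)]
        else:
            carriers = [sample_id]
        for s in carriers:
            calls.append(SnvCall(var.CHROM, var.POS, var.REF, alt, s))
    vcf.close()
    return calls


_SV_COLUMNS = {"chrom1", "pos1", "chrom2", "pos2", "type", "homology", "sample"}


def read_sv_table(path) -> list[SvCall]:
    """Read SV calls from a BEDPE-like TSV with header columns
    chrom1, pos1, chrom2, pos2, type, homology, sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = _SV_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SV table columns {sorted(missing)}")
    return [
        SvCall(str(r.chrom1), int(r.pos1), str(r.chrom2), int(r.pos2),
               str(r.type), int(r.homology), str(r.sample))
        for r in df.itertuples(index=False)
    ]


# -- fit serialization -----------------------------------------------------


def _space_to_dict(space: CategorySpace) -> dict:
    return {"modality": space.modality, "labels": list(space.labels),
            "encoding": space.encoding,
            "feature_arity": list(space.feature_arity)}


def save_fit(fit: MmctmFit, out_dir) -> None:
    """Serialize a fit as a directory of TSVs plus JSON run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (sig, probs) in enumerate(zip(fit.signatures, fit.sample_probs)):
        tag = f"{i}_{sig.category_space.modality.lower()}"
        sig.to_frame().to_csv(out / f"signatures_{tag}.tsv", sep="\t")
        probs.to_frame().to_csv(out / f"theta_{tag}.tsv", sep="\t")
    if fit.prior is not None:
        np.savetxt(out / "mu.tsv", fit.prior.mu[None, :], delimiter="\t")
        np.savetxt(out / "sigma.tsv", fit.prior.sigma, delimiter="\t")
    np.savetxt(out / "elbo_trace.tsv", np.asarray(fit.elbo_trace), delimiter="\t")
    engine = fit._engine
    gammas = []
    if engine is not None:
        mods = [engine.mod] if hasattr(engine, "mod") else engine.mods
        for i, mod in enumerate(mods):
            per_feature = []
            for f, g in enumerate(mod.gamma):
                fname = f"gamma_{i}_{f}.tsv"
                np.savetxt(out / fname, g, delimiter="\t")
                per_feature.append(fname)
            gammas.append(per_feature)
    meta = {
        "config": dataclasses.asdict(fit.config),
        "metadata": fit.metadata,
        "training_predictive_ll": fit.training_predictive_ll,
        "category_spaces": [_space_to_dict(s.category_space)
                            for s in fit.signatures],
        "sample_ids": fit.sample_probs[0].sample_ids,
        "gamma_files": gammas,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))


def load_fit(fit_dir) -> MmctmFit:
    """Load a serialized fit, reconstructing an inference-capable engine."""
    from .models.engine import VariationalCTM, VariationalLDA

    out = Path(fit_dir)
    meta = json.loads((out / "run_metadata.json").read_text())
    cfg = meta["config"]
    cfg["k"] = tuple(cfg["k"])
    config = ModelConfig(**cfg)
    spaces = [CategorySpace(d["modality"], tuple(d["labels"]), d["encoding"],
                            tuple(d["feature_arity"]))
              for d in meta["category_spaces"]]
    signatures, sample_probs = [], []
    for i, space in enumerate(spaces):
        tag = f"{i}_{space.modality.lower()}"
        sig_df = pd.read_csv(out / f"signatures_{tag}.tsv", sep="\t", index_col=0)
        signatures.append(SignatureSet(space, sig_df.to_numpy(),
                                       names=list(sig_df.index)))
        th_df = pd.read_csv(out / f"theta_{tag}.tsv", sep="\t", index_col=0)
        sample_probs.append(SampleSignatureProbs(
            space.modality, list(th_df.index.astype(str)), th_df.to_numpy(),
            signature_names=list(th_df.columns)))
    prior = None
    if (out / "mu.tsv").exists():
        mu = np.atleast_1d(np.loadtxt(out / "mu.tsv", delimiter="\t"))
        sigma = np.atleast_2d(np.loadtxt(out / "sigma.tsv", delimiter="\t"))
        prior = GaussianPrior(mu, sigma)
    elbo = np.atleast_1d(np.loadtxt(out / "elbo_trace.tsv", delimiter="\t"))
    engine = None
    if meta["gamma_files"]:
        gammas = [[np.atleast_2d(np.loadtxt(out / f, delimiter="\t"))
                   for f in files] for files in meta["gamma_files"]]
        # engine skeleton over unit counts; fitted parameters overwrite it
        dummies = [CountMatrix(meta["sample_ids"][:1], sp,
                               np.ones((1, len(sp)), dtype=int))
                   for sp in spaces]
        rng = np.random.default_rng(0)
        if config.model in ("lda", "ilda"):
            engine = VariationalLDA(dummies[0], config.k[0], config.alpha,
                                    config.beta, rng)
            engine.mod.gamma = gammas[0]
        else:
            engine = VariationalCTM(dummies, config.k, config.beta, rng,
                                    config.fix_covariance_identity)
            for mod, g in zip(engine.mods, gammas):
                mod.gamma = g
            if prior is not None:
                engine.mu, engine.sigma = prior.mu.copy(), prior.sigma.copy()
    return MmctmFit(config, prior, signatures, sample_probs, elbo,
                    meta["training_predictive_ll"], meta["metadata"],
                    _engine=engine)
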