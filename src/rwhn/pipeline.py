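"""End-to-end orchestration: preprocess → build → walk → statistics.

A :class:`PipelineConfig` (YAML-loadable) carries every input path and
numeric parameter with the method's defaults. :func:`run_pipeline` writes a
rankings TSV, optional permutation and ORA TSVs, and a JSON run manifest
(parameters, input checksums, seed, per-stage node/edge counts) sufficient
to reproduce the run byte for byte. One global seed derives all stage seeds
through a named counter, so individual stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import RWHNParams, run_rwhn
from .errors import ConfigError, UnknownParameter
from .io_formats import (
    read_gmt,
    read_obo,
    read_ppi_edges,
    read_quant_table,
    write_rankings,
)
from .netbuild import assemble_multilayer, build_protein_subnetwork
from .preprocess import (
    cluster_profiles,
    filter_regulated_sites,
    impute_left_censored,
    quantile_normalize,
    select_k,
)
from .stats import ora, permutation_significance, ranking_to_rankmap, weighted_tau

logger = logging.getLogger("rwhn")

_STAGES = ("impute", "cluster", "build", "permute")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run (method defaults)."""

    quant: str = ""
    ppi: str = ""
    gmt: str = ""
    obo: str = ""
    mode: str = "go"  # or "kegg"
    outdir: str = "rwhn_out"
    seed: int = 0
    # quant-table parsing
    id_columns: tuple = ("protein", "residue", "position")
    # preprocessing
    max_missing: int = 1
    ratio_lo: float = 0.5
    ratio_hi: float = 2.0
    censor_quantile: float = 0.01
    quantile_normalize: bool = False
    cluster_method: str = "fcm"
    k: int | None = None
    k_min: int = 2
    k_max: int = 8
    k_selection: str = "silhouette"
    fuzzifier: float = 2.0
    # network construction
    string_channel: str = "experimental"
    string_threshold: float = 0.4
    corr_threshold: float = 0.99
    corr_squared: bool = True
    funsim_threshold: float = 0.7
    freq_cutoff: float = 0.05
    redundancy_cutoff: float = 0.9
    enrich_alpha: float = 0.05
    louvain_resolution: float = 1.0
    kegg_metric: str = "overlap"
    # walk
    lambda_: float = 0.7
    r: float = 0.7
    eta_p: float = 0.7
    eta_f: float = 0.3
    tol: float = 1e-10
    max_iter: int = 10000
    top_fraction: float = 0.05
    protein_split: str = "half"
    # statistics
    n_perm: int = 0  # 0 disables the permutation control
    ora_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("quant", "ppi", "gmt"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(path).exists():
                raise ConfigError(f"config field {name!r}: no such file {path}")
        if self.mode not in ("go", "kegg"):
            raise ConfigError(f"mode must be 'go' or 'kegg', got {self.mode!r}")
        if self.mode == "go":
            if not self.obo:
                raise ConfigError("config field 'obo' is required in go mode")
            if not Path(self.obo).exists():
                raise ConfigError(f"config field 'obo': no such file {self.obo}")

    def walk_params(self) -> RWHNParams:
        return RWHNParams(
            lambda_=self.lambda_,
            r=self.r,
            eta_p=self.eta_p,
            eta_f=self.eta_f,
            tol=self.tol,
            max_iter=self.max_iter,
            top_fraction=self.top_fraction,
            protein_split=self.protein_split,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _prepare(config: PipelineConfig):
    """Shared read + preprocess + build steps; returns (qt, clusters, net, lib, counts)."""
    qt = read_quant_table(config.quant, id_columns=tuple(config.id_columns))
    ppi = read_ppi_edges(config.ppi, config.string_channel, config.string_threshold)
    lib = read_gmt(config.gmt)
    dag = read_obo(config.obo) if config.mode == "go" else None

    n_input = qt.n_sites
    qt = filter_regulated_sites(qt, config.max_missing, config.ratio_lo, config.ratio_hi)
    qt = impute_left_censored(qt, derive_seed(config.seed, "impute"), config.censor_quantile)
    if config.quantile_normalize:
        qt = quantile_normalize(qt)
    k = config.k
    cluster_seed = derive_seed(config.seed, "cluster")
    if k is None:
        k = select_k(
            qt,
            range(config.k_min, min(config.k_max, qt.n_sites - 1) + 1),
            config.k_selection,
            cluster_seed,
        )
    clusters = cluster_profiles(
        qt, k, config.cluster_method, config.fuzzifier, cluster_seed
    )
    net = assemble_multilayer(
        qt,
        clusters,
        ppi,
        lib,
        dag,
        mode=config.mode,
        corr_threshold=config.corr_threshold,
        corr_squared=config.corr_squared,
        funsim_threshold=config.funsim_threshold,
        freq_cutoff=config.freq_cutoff,
        redundancy_cutoff=config.redundancy_cutoff,
        alpha=config.enrich_alpha,
        resolution=config.louvain_resolution,
        kegg_metric=config.kegg_metric,
        seed=derive_seed(config.seed, "build"),
    )
    counts = {"input_sites": n_input, "filtered_sites": qt.n_sites, "k": k}
    counts.update(net.summary())
    return qt, clusters, net, lib, ppi, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle into ``config.outdir``.

    Returns the manifest dict. Output files: ``rankings.tsv`` always;
    ``permutation.tsv`` when ``n_perm > 0``; ``ora.tsv`` always;
    ``manifest.json`` last (its presence marks a completed run).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    qt, clusters, net, lib, ppi, counts = _prepare(config)
    logger.info("network built: %s", counts)

    result = run_rwhn(net, clusters, config.walk_params())
    write_rankings(result, outdir / "rankings.tsv", net.term_names)
    logger.info("rankings written (%.1fs)", time.monotonic() - t0)

    if config.n_perm > 0:
        stats = permutation_significance(
            net,
            clusters,
            config.walk_params(),
            config.n_perm,
            derive_seed(config.seed, "permute"),
        )
        rows = stats.to_rows()
        with open(outdir / "permutation.tsv", "w") as fh:
            cols = list(rows[0]) if rows else ["seed_cluster", "term_id"]
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(repr(row[c]) if isinstance(row[c], float) else str(row[c]) for c in cols) + "\n")
        logger.info("permutation control written (%.1fs)", time.monotonic() - t0)

    universe = set(lib.effective_universe()) | set(net.proteins)
    with open(outdir / "ora.tsv", "w") as fh:
        fh.write("seed_cluster\tterm_id\tterm_name\toverlap\tterm_size\tp\tq\n")
        for c in clusters.cluster_ids():
            prots = {s.protein for s in clusters.sites_in(c)}
            for term, k_, K, p, q in ora(prots, lib, universe, config.ora_alpha):
                fh.write(
                    f"{c}\t{term}\t{lib.name_of(term)}\t{k_}\t{K}\t{p!r}\t{q!r}\n"
                )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("quant", "ppi", "gmt", "obo")
            if getattr(config, name)
        },
        "counts": counts,
        "elapsed_s": round(time.monotonic() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


_SWEEPABLE = ("lambda", "r", "eta_p", "eta_f", "string_threshold")


def sweep_parameters(config: PipelineConfig, parameter: str, grid) -> list[dict]:
    """Rerun the pipeline over a parameter grid; compare rankings to default.

    For each grid value, reports the hyperbolically weighted tau between the
    per-cluster rankings of the modified and the default run (averaged over
    clusters). For ``string_threshold`` the number of connected components
    of the protein layer is reported as well.
    """
    if parameter not in _SWEEPABLE:
        raise UnknownParameter(
            f"parameter must be one of {_SWEEPABLE}, got {parameter!r}"
        )
    config.validate()
    attr = "lambda_" if parameter == "lambda" else parameter

    qt, clusters, net, lib, ppi, _ = _prepare(config)
    base_result = run_rwhn(net, clusters, config.walk_params())

    rows: list[dict] = []
    for value in grid:
        import dataclasses

        cfg = dataclasses.replace(config, **{attr: float(value)})
        row: dict = {"parameter": parameter, "value": float(value)}
        if parameter == "string_threshold":
            import networkx as nx

            ppi_v = read_ppi_edges(cfg.ppi, cfg.string_channel, cfg.string_threshold)
            _, clusters_v, net_v, _, _, _ = _prepare(cfg)
            app = build_protein_subnetwork(ppi_v, qt.proteins())
            g = nx.from_numpy_array(app.matrix)
            row["protein_components"] = nx.number_connected_components(g)
            result_v = run_rwhn(net_v, clusters_v, cfg.walk_params())
        else:
            result_v = run_rwhn(net, clusters, cfg.walk_params())
        taus = []
        for c in base_result.clusters:
            base_map = ranking_to_rankmap(base_result, c)
            var_map = ranking_to_rankmap(result_v, c)
            common = set(base_map) & set(var_map)
            if len(common) >= 2:
                taus.append(
                    weighted_tau(
                        {t: base_map[t] for t in common},
                        {t: var_map[t] for t in common},
                    )
                )
        row["weighted_tau_vs_default"] = float(np.mean(taus)) if taus else float("nan")
        rows.append(row)
    return rows
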