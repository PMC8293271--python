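"""Method/trait reconciliation, correlation networks, full pipeline.

Biomarker lists from the bucket and metabolite methods (and across the
two traits) are reconciled with Venn set logic after canonicalizing
metabolite naming variants. Correlation networks connect biomarker
relative concentrations with each other and with the trait node, keeping
edges whose Pearson |r| clears a threshold. ``run_pipeline`` chains
simulation, preprocessing, chemometrics, both biomarker methods, Venn
reconciliation and networks into one deterministic, file-writing run.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from hepamark import chemometrics as chem
from hepamark import bucket_method as bm
from hepamark import metabolite_method as mm
from hepamark import preprocess as pp
from hepamark import synthetic as syn

__all__ = [
    "VennResult",
    "canonical_name",
    "venn_compare",
    "build_network",
    "network_edge_list",
    "default_config",
    "run_pipeline",
    "PipelineResult",
]


def _load_synonyms() -> dict[str, str]:
    ref = resources.files("hepamark").joinpath("data/synonyms.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["variant"], df["canonical"]))


_SYNONYMS = _load_synonyms()


def canonical_name(name: str) -> str:
    """Case-insensitive canonical metabolite name.

    Lower-cases, collapses whitespace, then applies the packaged synonym
    table (e.g. "guanidino acetic acid" -> "guanidinoacetic acid").
    """
    key = re.sub(r"\s+", " ", str(name).strip().lower())
    return _SYNONYMS.get(key, key)


@dataclass
class VennResult:
    """Exact two-set partition of canonicalized name sets."""

    only_a: set[str]
    common: set[str]
    only_b: set[str]
    label_a: str = "a"
    label_b: str = "b"

    @property
    def union(self) -> set[str]:
        return self.only_a | self.common | self.only_b

    def sizes(self) -> dict[str, int]:
        return {
            f"only_{self.label_a}": len(self.only_a),
            "common": len(self.common),
            f"only_{self.label_b}": len(self.only_b),
        }


def venn_compare(a: Iterable[str], b: Iterable[str], labels=("a", "b")) -> VennResult:
    """Partition two biomarker name lists into only-a / common / only-b."""
    ca = {canonical_name(x) for x in a}
    cb = {canonical_name(x) for x in b}
    return VennResult(
        only_a=ca - cb, common=ca & cb, only_b=cb - ca, label_a=labels[0], label_b=labels[1]
    )


def build_network(
    rc_table: pd.DataFrame,
    y,
    trait_name: str = "Y",
    threshold: float = 0.4,
) -> nx.Graph:
    """Pearson correlation network of biomarker RCs plus one trait node.

    Edges with |r| >= threshold are kept with their signed correlation as
    the ``weight`` attribute and ``sign`` in {-1, +1}. Constant columns
    have undefined correlations: the node stays, flagged ``constant``,
    with no edges.
    """
    if rc_table.shape[1] < 2:
        raise ValueError("need at least 2 biomarkers for a network")
    df = rc_table.copy()
    df[trait_name] = np.asarray(y, dtype=float)

    g = nx.Graph(threshold=threshold, trait=trait_name)
    constant = {c for c in df.columns if df[c].std(ddof=0) == 0}
    for c in df.columns:
        g.add_node(
            str(c), kind="trait" if c == trait_name else "metabolite", constant=c in constant
        )
    corr = df.corr(method="pearson")
    cols = list(df.columns)
    for i, u in enumerate(cols):
        for v in cols[i + 1 :]:
            if u in constant or v in constant:
                continue
            r = float(corr.loc[u, v])
            if abs(r) >= threshold:
                g.add_edge(str(u), str(v), weight=r, sign=int(np.sign(r)))
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "r": d["weight"], "sign": d["sign"]}
        for u, v, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


# ---------------------------------------------------------------------------
# pipeline


def default_config() -> dict:
    """Default synthetic-study configuration (schema version 1)."""
    return {
        "schema_version": 1,
        "seed": 0,
        "traits": ["LW", "TY"],
        "simulate": {
            "n_per_day": 16,
            "days": [6, 8, 10, 12],
            "target_corr": -0.80,
            "baseline": 1.0,
            "cv_noise": 0.1,
            "effects": {
                name: {"trait": t, "sign": s, "magnitude": m}
                for name, (t, s, m) in syn.default_effects().items()
            },
        },
        "render": {
            "grid_step": 0.001,
            "linewidth": 0.002,
            "shift_jitter_sd": 0.002,
            "noise_sd": 0.5,
        },
        "buckets": {
            "lo": 0.5,
            "hi": 10.0,
            "width": 0.01,
            "exclusions": [[4.5, 5.1], [3.2, 3.35]],
        },
        "thresholds": {
            "vip": 1.0,
            "bh_bucket": 0.05,
            "bh_sig": 0.05,
            "bh_tendency": 0.1,
            "shift_tol": 0.005,
            "network_r": 0.4,
            "presence_frac": 0.5,
        },
        "cv_folds": 7,
        "n_permutations": 0,
    }


@dataclass
class TraitResult:
    trait: str
    pls_summary: dict
    bucket_stats: pd.DataFrame
    evidence: list
    bucket_records: pd.DataFrame
    metabolite_records: pd.DataFrame
    bucket_list: list[str]
    metabolite_list: list[str]
    venn: VennResult
    network: nx.Graph
    rc_table: pd.DataFrame
    permutation: chem.PermutationResult | None = None

    @property
    def biomarkers(self) -> set[str]:
        return {canonical_name(m) for m in self.bucket_list} | {
            canonical_name(m) for m in self.metabolite_list
        }


@dataclass
class PipelineResult:
    config: dict
    pheno: pd.DataFrame
    concentrations: pd.DataFrame | None
    buckets: pp.BucketTable
    traits: dict[str, TraitResult]
    trait_venn: VennResult | None
    outlier_flags: Mapping[str, np.ndarray] = field(default_factory=dict)


def _deep_update(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def _analyze_trait(
    trait: str,
    pheno: pd.DataFrame,
    normalized: pp.BucketTable,
    library: syn.FingerprintLibrary,
    templates: pd.DataFrame,
    cfg: dict,
) -> TraitResult:
    th = cfg["thresholds"]
    y = pheno.set_index("sample_id").loc[normalized.values.index, trait].to_numpy()

    scaled = pp.pareto_scale(normalized.values)
    model = chem.fit_pls1(scaled.scaled, y)
    q2, rmsecv = chem.q2_rmsecv(normalized.values, y, folds=cfg["cv_folds"], seed=cfg["seed"])
    rmsee_val = chem.rmsee(model, scaled.scaled, y)
    perm = None
    if cfg.get("n_permutations", 0) > 0:
        perm = chem.permutation_validation(
            normalized.values, y, n_perm=cfg["n_permutations"], seed=cfg["seed"],
            folds=cfg["cv_folds"],
        )

    stats_df = bm.make_bucket_stats(normalized, y, model.vip)
    evidence = bm.annotate_vip_buckets(
        stats_df, library, vip_thresh=th["vip"], bh_thresh=th["bh_bucket"],
        shift_tol=th["shift_tol"], bucket_width=normalized.width,
    )
    candidates = bm.candidate_metabolites(evidence)
    if candidates:
        rc = bm.compute_rc_table(normalized, candidates, library, shift_tol=th["shift_tol"])
        bucket_records = bm.qualify_bucket_biomarkers(
            rc, y, trait=trait, thresh_sig=th["bh_sig"], thresh_tend=th["bh_tendency"]
        )
        bucket_list = list(bucket_records.loc[bucket_records["status"] != "rejected", "metabolite"])
    else:
        rc = pd.DataFrame(index=normalized.values.index)
        bucket_records = bm.qualify_bucket_biomarkers(rc, y, trait=trait)
        bucket_list = []

    conc = mm.unmix_study(normalized, templates)
    retained = mm.presence_filter(conc, pheno, min_frac=th["presence_frac"])
    metabolite_records = mm.qualify_metabolite_biomarkers(
        conc[retained], y, trait=trait, vip_thresh=th["vip"], bh_thresh=th["bh_sig"]
    )
    metabolite_list = list(
        metabolite_records.loc[metabolite_records["qualified"], "metabolite"]
    )

    venn = venn_compare(bucket_list, metabolite_list, labels=("bucket", "metabolite"))
    union = sorted({m for m in bucket_list} | {m for m in metabolite_list})
    # Network RCs are computed with the bucket data for every biomarker
    # of the trait, whichever method found it.
    rc_all = bm.compute_rc_table(normalized, union, library, shift_tol=th["shift_tol"]) if len(union) >= 2 else rc
    network = (
        build_network(rc_all, y, trait_name=trait, threshold=th["network_r"])
        if rc_all.shape[1] >= 2
        else nx.Graph(trait=trait)
    )

    pls_summary = {
        "trait": trait,
        "n_components": 1,
        "r2x": model.r2x,
        "r2y": model.r2y,
        "q2": q2,
        "rmsee": rmsee_val,
        "rmsecv": rmsecv,
        "n_vip_buckets": int((model.vip > th["vip"]).sum()),
    }
    if perm is not None:
        pls_summary.update(
            {
                "perm_intercept_r2y": perm.intercept_r2y,
                "perm_intercept_q2": perm.intercept_q2,
                "n_permutations": perm.n_perm,
            }
        )
    return TraitResult(
        trait=trait,
        pls_summary=pls_summary,
        bucket_stats=stats_df,
        evidence=evidence,
        bucket_records=bucket_records,
        metabolite_records=metabolite_records,
        bucket_list=bucket_list,
        metabolite_list=metabolite_list,
        venn=venn,
        network=network,
        rc_table=rc,
        permutation=perm,
    )


def run_pipeline(
    config: Mapping | str | Path | None = None,
    out_dir: str | Path | None = None,
    pheno: pd.DataFrame | None = None,
    spectra=None,
) -> PipelineResult:
    """Run the full two-method biomarker pipeline.

    With no measured inputs the study is simulated from the config's
    ``simulate`` block. Supplying ``pheno`` and ``spectra`` analyzes
    measured data instead. When ``out_dir`` is given every table, the
    Venn partitions, the networks and a run log (seed, thresholds) are
    written there; identical config + seed give byte-identical outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _deep_update(default_config(), config or {})
    seed = cfg["seed"]
    library = syn.packaged_fingerprints()

    conc = None
    if pheno is None or spectra is None:
        sim = cfg["simulate"]
        pheno = syn.generate_phenotypes(
            n_per_day=sim["n_per_day"], days=sim["days"], seed=seed,
            target_corr=sim["target_corr"],
        )
        effects = {
            name: (e["trait"], e["sign"], e["magnitude"])
            for name, e in sim["effects"].items()
        }
        conc = syn.simulate_concentrations(
            pheno, effects, metabolites=library.non_decoys,
            baseline=sim["baseline"], cv_noise=sim["cv_noise"], seed=seed,
        )
        spectra = syn.render_study(conc, library, seed=seed, **cfg["render"])

    bcfg = cfg["buckets"]
    exclusions = [tuple(e) for e in bcfg["exclusions"]]
    raw = pp.bucket_spectra(spectra, bcfg["lo"], bcfg["hi"], bcfg["width"], exclusions)
    normalized = pp.normalize_buckets(raw)
    templates = mm.build_templates(
        library, bcfg["lo"], bcfg["hi"], bcfg["width"], exclusions,
        grid_step=cfg["render"]["grid_step"], linewidth=cfg["render"]["linewidth"],
    )

    scaled = pp.pareto_scale(normalized.values)
    outlier_flags = {"all": chem.pca_outlier_screen(scaled.scaled).flags}

    traits: dict[str, TraitResult] = {}
    for trait in cfg["traits"]:
        traits[trait] = _analyze_trait(trait, pheno, normalized, library, templates, cfg)

    tv = None
    if {"LW", "TY"} <= set(traits):
        tv = venn_compare(traits["LW"].biomarkers, traits["TY"].biomarkers, labels=("LW", "TY"))

    result = PipelineResult(
        config=cfg, pheno=pheno, concentrations=conc, buckets=normalized,
        traits=traits, trait_venn=tv, outlier_flags=outlier_flags,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.pheno.to_csv(out / "phenotypes.csv", index=False)
    if result.concentrations is not None:
        result.concentrations.to_csv(out / "true_concentrations.csv")
    result.buckets.to_csv(out / "buckets_normalized.csv")

    summary: dict = {"config": result.config, "traits": {}}
    for trait, tr in result.traits.items():
        tr.bucket_stats.to_csv(out / f"{trait}_bucket_stats.csv", index_label="bucket")
        bm.evidence_table(tr.evidence).to_csv(out / f"{trait}_peak_evidence.csv", index=False)
        tr.bucket_records.to_csv(out / f"{trait}_bucket_biomarkers.csv", index=False)
        tr.metabolite_records.to_csv(out / f"{trait}_metabolite_biomarkers.csv", index=False)
        network_edge_list(tr.network).to_csv(out / f"{trait}_network_edges.tsv", sep="\t", index=False)
        summary["traits"][trait] = {
            "pls": tr.pls_summary,
            "bucket_biomarkers": sorted(tr.bucket_list),
            "metabolite_biomarkers": sorted(tr.metabolite_list),
            "venn": {k: sorted(v) for k, v in
                     {"bucket_only": tr.venn.only_a, "common": tr.venn.common,
                      "metabolite_only": tr.venn.only_b}.items()},
        }
    if result.trait_venn is not None:
        summary["trait_venn"] = {
            "lw_only": sorted(result.trait_venn.only_a),
            "common": sorted(result.trait_venn.common),
            "ty_only": sorted(result.trait_venn.only_b),
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
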