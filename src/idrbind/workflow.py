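"""End-to-end training and prediction pipelines used by the CLI and tests."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from idrbind.annotations import (
    FUNCTIONS,
    AnnotatedProtein,
    tracks_to_regions,
    write_fasta,
    write_regions,
)
from idrbind.features import (
    DEFAULT_WS,
    FeatureVectorSet,
    WindowSpec,
    build_features,
    derive_window_size,
    select_features,
)
from idrbind.model import (
    BindingModel,
    PropensityProfile,
    load_model,
    predict,
    save_model,
    train,
)
from idrbind.profiles import build_profile_matrix
from idrbind.regions import BindingRegion, binarize, call_regions
from idrbind.scales import ScaleSet
from idrbind.transfer import DEFAULT_E_CUTOFF, merge, search, transfer

logger = logging.getLogger(__name__)

LIBRARY_FASTA = "library.fasta"
LIBRARY_REGIONS = "library_regions.tsv"


def _profile_matrices(proteins, scale_set, disorder_provider, secstruct_provider):
    return {
        p.id: build_profile_matrix(
            p, scale_set=scale_set,
            disorder_provider=disorder_provider,
            secstruct_provider=secstruct_provider,
        )
        for p in proteins
    }


def corpus_window_spec(
    proteins: list[AnnotatedProtein], function: str, ws_override: int | None = None
) -> WindowSpec:
    """Window size from the 20th centile of the corpus region lengths,
    falling back to the documented defaults when no regions exist."""
    if ws_override is not None:
        return WindowSpec(function, ws_override)
    lengths = [
        r.length for p in proteins for r in tracks_to_regions(p)
        if r.function == function
    ]
    ws = derive_window_size(lengths) if lengths else DEFAULT_WS[function]
    return WindowSpec(function, ws)


def train_corpus(
    proteins: list[AnnotatedProtein],
    out_dir: str | Path | None = None,
    ridge_lambda: float = 1.0,
    ws_overrides: dict[str, int] | None = None,
    relevance_min_auc: float = 0.55,
    redundancy_max_abs_corr: float = 0.7,
    scale_set: ScaleSet | None = None,
    disorder_provider: str = "bundled",
    secstruct_provider: str = "bundled",
) -> dict[str, BindingModel]:
    """Train one model per function; optionally persist models + library.

    Functions without positive residues are skipped with a warning.
    """
    ws_overrides = ws_overrides or {}
    profiles = _profile_matrices(proteins, scale_set, disorder_provider, secstruct_provider)
    out = Path(out_dir) if out_dir is not None else None
    library_ref = ""
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(proteins, out / LIBRARY_FASTA)
        records = [r for p in proteins for r in tracks_to_regions(p)]
        write_regions(records, out / LIBRARY_REGIONS)
        library_ref = LIBRARY_FASTA

    models: dict[str, BindingModel] = {}
    for function in FUNCTIONS:
        labels_total = sum(int(p.track(function).sum()) for p in proteins)
        if labels_total == 0:
            logger.warning("no positive residues for %s: model skipped", function)
            continue
        spec = corpus_window_spec(proteins, function, ws_overrides.get(function))
        parts = [
            build_features(profiles[p.id], spec, labels=p.track(function))
            for p in proteins
        ]
        fvs = FeatureVectorSet.concatenate(parts)
        selected = select_features(fvs, relevance_min_auc, redundancy_max_abs_corr)
        if not selected:
            logger.warning("no feature selected for %s: model skipped", function)
            continue
        logger.info("%s: ws=%d, %d/%d features selected", function, spec.ws,
                    len(selected), len(fvs.feature_ids))
        model = train(fvs.select(selected), function, spec,
                      ridge_lambda=ridge_lambda, training_library_ref=library_ref)
        models[function] = model
        if out is not None:
            save_model(model, out / f"model_{function}.txt")
    return models


def load_models(models_dir: str | Path) -> tuple[dict[str, BindingModel], list[AnnotatedProtein] | None]:
    """Load saved models and, if present, the training library with tracks."""
    from idrbind.annotations import read_fasta, read_regions, regions_to_tracks

    models_dir = Path(models_dir)
    models = {}
    for function in FUNCTIONS:
        path = models_dir / f"model_{function}.txt"
        if path.exists():
            models[function] = load_model(path)
    library = None
    fasta = models_dir / LIBRARY_FASTA
    if fasta.exists():
        library = read_fasta(fasta)
        regions_path = models_dir / LIBRARY_REGIONS
        if regions_path.exists():
            regions_to_tracks(read_regions(regions_path), library)
    return models, library


def predict_proteins(
    proteins: list[AnnotatedProtein],
    models: dict[str, BindingModel],
    library: list[AnnotatedProtein] | None = None,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    scale_set: ScaleSet | None = None,
    disorder_provider: str = "bundled",
    secstruct_provider: str = "bundled",
) -> dict[str, PropensityProfile]:
    """Full pipeline: regression propensities, then alignment transfer and
    the (1+p)/2 merge when a library is given and e_cutoff > 0."""
    profiles = _profile_matrices(proteins, scale_set, disorder_provider, secstruct_provider)
    use_transfer = library is not None and e_cutoff > 0
    library_tracks = (
        {p.id: {f: p.track(f) for f in FUNCTIONS} for p in library}
        if use_transfer else {}
    )
    results: dict[str, PropensityProfile] = {}
    for p in proteins:
        if len(p) < 5:
            logger.warning("sequence %s shorter than 5 residues: windows fully truncated", p.id)
        prof = PropensityProfile(protein_id=p.id)
        hits = search(p, library) if use_transfer else []
        transferred = (
            transfer(p, hits, library_tracks, e_cutoff=e_cutoff)
            if use_transfer else {}
        )
        for function, model in models.items():
            fvs = build_features(profiles[p.id], model.window_spec)
            reg_p = predict(model, fvs)
            t = transferred.get(function)
            if t is not None:
                prof.set(function, merge(reg_p, t), t)
            else:
                prof.set(function, reg_p)
        results[p.id] = prof
    return results


def call_all_regions(
    profiles: dict[str, PropensityProfile],
    cutoff: float = 0.5,
    min_len: int = 4,
) -> list[BindingRegion]:
    regions: list[BindingRegion] = []
    for pid in sorted(profiles):
        prof = profiles[pid]
        for function in FUNCTIONS:
            if function not in prof.propensities:
                continue
            p = prof.propensities[function]
            regions.extend(
                call_regions(binarize(p, cutoff), pid, function, p, min_len)
            )
    return regions


def write_prediction_table(
    proteins: list[AnnotatedProtein],
    profiles: dict[str, PropensityProfile],
    path: str | Path,
    cutoff: float = 0.5,
) -> None:
    """Per-residue TSV: propensities and binary calls for the three functions."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tp_rna\tp_dna\tp_prot\tb_rna\tb_dna\tb_prot\n")
        for prot in proteins:
            prof = profiles[prot.id]
            cols = {}
            for f in FUNCTIONS:
                p = prof.propensities.get(f)
                cols[f] = p if p is not None else np.full(len(prot), np.nan)
            for i, aa in enumerate(prot.sequence):
                ps = [cols[f][i] for f in FUNCTIONS]
                bs = [
                    ("1" if np.isfinite(v) and v >= cutoff else "0") for v in ps
                ]
                p_str = "\t".join("nan" if not np.isfinite(v) else f"{v:.6f}" for v in ps)
                fh.write(f"{prot.id}\t{i + 1}\t{aa}\t{p_str}\t" + "\t".join(bs) + "\n")


def read_prediction_table(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Read the per-residue prediction TSV back into per-function score maps."""
    per: dict[str, dict[str, list[float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pid = parts[0]
            d = per.setdefault(pid, {"rna": [], "dna": [], "protein": []})
            d["rna"].append(float(parts[3]))
            d["dna"].append(float(parts[4]))
            d["protein"].append(float(parts[5]))
    return {
        pid: {f: np.array(v) for f, v in d.items()} for pid, d in per.items()
    }
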