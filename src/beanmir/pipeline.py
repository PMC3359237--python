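"""End-to-end orchestration of the discovery pipeline.

Two entry points:

* :func:`run_synthetic` — generate seeded synthetic reference sets and
  libraries, run every stage (ncRNA filter, exact annotation, conservation
  filter, isomiR chain, precursor search/validation, novel scoring, target
  scan, family expression), and score the run against the planted truth.

* :func:`run_fixture_analysis` — run the stages that the bundled
  common-bean tables support end-to-end: the conservation filter, the
  locus/correlation analysis, the isomiR chain with family promotion, and
  the family expression clustering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

from . import conserved as cons
from . import expression as expr
from . import fixtures
from . import hairpin as hp
from . import isoforms as iso
from . import synthdata as synth
from . import targets as tgt
from .core_io import LibrarySet, write_table
from .energy import FoldParams


def run_synthetic(cfg: synth.SimConfig, outdir: str | Path | None = None,
                  fold_params: FoldParams | None = None) -> dict:
    """Run the full pipeline on one synthetic study; returns a results dict
    (stage outputs, recovery metrics, manifest)."""
    fold_params = fold_params or FoldParams()
    refsets, libset, sizes = synth.simulate(cfg)
    truth = refsets.truth
    results: dict = {"run_id": truth.run_id, "library_sizes": sizes}

    refs = cons.dedupe_refs(refsets.matures)
    filtered, removed = cons.filter_ncrna(libset, refsets.ncrna, refs)
    results["ncrna_removed"] = len(removed)

    hits, residual = cons.annotate_exact(filtered, refs)
    kept, discarded = cons.conservation_filter(hits)
    results["kept_hits"], results["discarded_hits"] = kept, discarded

    conserved_families = {h.ref.family for h in kept if not h.ref.is_star}
    ref_totals = {h.ref.name: h.total for h in hits}
    retained, candidates = iso.call_isomirs(residual, refs, ref_totals,
                                            conserved_families)
    results["retained_variants"] = retained
    promoted = iso.promote_families(retained, conserved_families)
    results["promoted_families"] = promoted

    # precursor search + validation for every annotated (non-star) miRNA
    validated: dict[str, bool] = {}
    iso_seqs = {c.variant for c in retained}
    for hit in hits:
        if hit.ref.is_star:
            continue
        ok = False
        for cand in hp.find_precursor_candidates(hit.ref.sequence, refsets.ests):
            hp.validate_hairpin(cand, fold_params)
            if cand.verdict:
                ok = True
                break
        validated[hit.ref.name] = ok
    results["validated_precursors"] = validated
    rescued = [h for h in discarded
               if not h.ref.is_star and validated.get(h.ref.name)]
    results["rescued_hits"] = rescued

    # novel miRNAs from the residual pool left after isomiR analysis: every
    # tag identified as a variant of a known miRNA (retained or not) is out
    variant_seqs = iso_seqs | {c.variant for c in candidates}
    residual2 = residual.without(variant_seqs)
    novel_tags = iso.prefilter_tags(residual2.sorted_tags())
    seen_windows: set[tuple[str, tuple[int, int]]] = set()
    novel: list[hp.NovelCandidate] = []
    all_residual = residual2.sorted_tags()
    for tag in novel_tags:
        for cand in hp.find_precursor_candidates(tag.sequence, refsets.ests):
            key = (cand.source_id, cand.window)
            if key in seen_windows:
                continue
            seen_windows.add(key)
            hp.validate_hairpin(cand, fold_params)
            if not cand.verdict:
                continue
            scored = hp.score_novel(cand, all_residual)
            if scored is not None and scored.score >= hp.NOVEL_KEEP_THRESHOLD:
                novel.append(scored)
                break
    # one candidate per locus: keep the best-scoring window per EST/strand
    best_by_locus: dict[tuple[str, str], hp.NovelCandidate] = {}
    for c in novel:
        key = (c.precursor.source_id, c.precursor.strand)
        if key not in best_by_locus or c.score > best_by_locus[key].score:
            best_by_locus[key] = c
    novel = sorted(best_by_locus.values(), key=lambda c: -c.score)
    results["novel_candidates"] = novel

    # duplex target scan for every annotated mature miRNA
    mirnas = [(h.ref.name, h.ref.sequence) for h in hits if not h.ref.is_star]
    results["target_calls"] = tgt.scan_targets(mirnas, refsets.ests,
                                               params=fold_params)

    # family expression
    k = expr.pool_families(kept, rescued, retained, promoted,
                           libraries=cfg.organs)
    s = expr.size_factors(k)
    v = expr.vst(k, s)
    results["family_counts"] = k
    results["size_factors"] = s
    results["vst"] = v
    if k.shape[0] >= 2:
        results["hca"] = expr.hca(v.t)

    results["recovery"] = synth.ground_truth_report(truth, results)
    results["truth"] = truth

    if outdir is not None:
        _write_artifacts(results, cfg, Path(outdir))
    return results


def _write_artifacts(results: dict, cfg: synth.SimConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    libs = list(cfg.organs)

    rows = []
    for h in results["kept_hits"] + results["discarded_hits"]:
        row = {"reference": h.ref.name, "family": h.ref.family,
               "sequence": h.ref.sequence, "length": len(h.ref.sequence),
               "star": h.ref.is_star}
        row.update({lib: h.counts.get(lib, 0) for lib in libs})
        row.update({"total": h.total, "kept": h.kept})
        rows.append(row)
    rows.sort(key=lambda r: (-r["total"], r["reference"]))
    write_table(rows, outdir / "annotation.tsv")

    write_table(iso.variant_table_rows(results["retained_variants"], libs),
                outdir / "isomirs.tsv",
                columns=["variant", "reference", "class", "subs", "offset5",
                         "offset3", *libs, "total"])

    nrows = [{"est": c.precursor.source_id, "strand": c.precursor.strand,
              "window_start": c.precursor.window[0] + 1,
              "window_end": c.precursor.window[1],
              "mfe": round(c.precursor.structure.mfe, 2),
              "mature_reads": c.mature_reads, "star_reads": c.star_reads,
              "loop_reads": c.loop_reads,
              "inconsistent_reads": c.inconsistent_reads,
              "score": round(c.score, 3)}
             for c in results["novel_candidates"]]
    write_table(nrows, outdir / "novel_candidates.tsv",
                columns=["est", "strand", "window_start", "window_end", "mfe",
                         "mature_reads", "star_reads", "loop_reads",
                         "inconsistent_reads", "score"])

    trows = [{"mirna": c.hybrid.mirna, "est": c.hybrid.target_id,
              "site_start": c.hybrid.site[0] + 1, "site_end": c.hybrid.site[1],
              "mfe": round(c.hybrid.mfe, 2),
              "perfect_mfe": round(c.perfect_mfe, 2),
              "diagram": c.hybrid.diagram}
             for c in results["target_calls"]]
    write_table(trows, outdir / "targets.tsv",
                columns=["mirna", "est", "site_start", "site_end", "mfe",
                         "perfect_mfe", "diagram"])

    results["family_counts"].to_csv(outdir / "family_counts.tsv", sep="\t")
    results["vst"].t.round(6).to_csv(outdir / "vst.tsv", sep="\t")
    if "hca" in results:
        (outdir / "organ_tree.nwk").write_text(results["hca"].organ_newick() + "\n")
        (outdir / "heatmap_matrix.tsv").write_text(
            results["hca"].heatmap.round(6).to_csv(sep="\t"))

    manifest = {
        "config": _jsonable(asdict(cfg)),
        "library_sizes": results["library_sizes"],
        "recovery": results["recovery"],
        "promoted_families": sorted(results["promoted_families"]),
        "n_kept_hits": len(results["kept_hits"]),
        "n_retained_variants": len(results["retained_variants"]),
        "n_novel_candidates": len(results["novel_candidates"]),
        "n_target_calls": len(results["target_calls"]),
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_fixture_analysis() -> dict:
    """The bundled-table analysis: conservation numbers, locus correlations,
    the isomiR chain with promotion, and family expression clustering."""
    out: dict = {}
    mature = fixtures.conserved_mature_hits()
    star = fixtures.conserved_star_hits()
    kept, discarded = cons.conservation_filter(mature + star)
    out["kept"] = kept
    out["n_entries_retained"] = len(kept)
    out["n_star_retained"] = sum(1 for h in kept if h.ref.is_star)
    out["n_mature_families"] = len({h.ref.family for h in kept
                                    if not h.ref.is_star})

    loci = fixtures.family_loci_table()
    r_gma, r_gma2 = cons.pearson_loci(loci["pvu"], loci["gma"])
    r_mtr, r_mtr2 = cons.pearson_loci(loci["pvu"], loci["mtr"])
    out["loci_pearson_gma"] = r_gma
    out["loci_pearson_gma_2dp"] = r_gma2
    out["loci_pearson_mtr"] = r_mtr
    out["loci_pearson_mtr_2dp"] = r_mtr2

    # isomiR chain against the variant table's own reference set
    from .core_io import Tag
    rows = fixtures.isomir_fixture()
    refs = fixtures.isomir_reference_set()
    ref_totals = {}
    for row in rows:
        if row.role == "reference":
            for ref in refs:
                if ref.sequence == row.sequence:
                    ref_totals[ref.name] = row.total
    tags = [Tag(row.sequence, dict(row.counts)) for row in rows
            if row.role == "variant"]
    conserved_families = {h.ref.family for h in mature}
    retained, _ = iso.call_isomirs(tags, refs, ref_totals, conserved_families)
    out["retained_variants"] = retained
    out["n_retained_variants"] = len(retained)
    out["class_counts"] = {
        c: sum(1 for v in retained if v.var_class == c)
        for c in (iso.LENGTH, iso.NON_CONSERVED, iso.CONSERVED)}
    promoted = iso.promote_families(retained, conserved_families)
    out["promoted_families"] = promoted

    # family expression over the 29 conserved + promoted families
    k = expr.pool_families(kept, promoted_variants=retained,
                           promoted_families=promoted,
                           libraries=fixtures.FIXTURE_LIBRARIES)
    s = expr.size_factors(k)
    v = expr.vst(k, s)
    h = expr.hca(v.t)
    out["family_counts"] = k
    out["size_factors"] = s
    out["vst"] = v
    out["hca"] = h
    out["leaf_root_sisters"] = expr.first_merge_pair(
        h.organ_linkage, h.organ_labels, "LL", "RL")
    return out
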