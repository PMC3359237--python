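"""Ground-truthed synthetic reference sets and four-organ small-RNA libraries.

The generator emulates the statistical structure the analysis assumes so
that every stage is testable without external databases:

* planted miRNA genes whose hairpin precursors (mature arm, >= 8 nt loop,
  near-complementary star arm with up to two G:U-compatible substitutions,
  2-nt 3' overhang geometry) are embedded in EST-like sequences;
* a mature/mature-star reference set containing the planted matures plus
  decoy matures that receive no reads, and a separate set of "novel" genes
  absent from the reference;
* per-organ gene abundances that are negative-binomially dispersed around
  lognormal gene means with mildly organ-specific profiles;
* 3'-heterogeneous isomiRs (extensions, truncations, small shifts, single
  substitutions), star reads, and contamination from ncRNA fragments and
  random 16-30-mers whose length mixture produces the characteristic
  21/24-nt modes (24 nt the most diverse class);
* planted perfect and near-perfect (wobbled) target sites in EST
  sequences.

A single seeded random stream drives each run, so outputs are
byte-identical for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .conserved import MatureRef
from .core_io import LibrarySet, SequenceRecord, Tag, revcomp

_NT = np.array(list("ACGU"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic run."""

    n_genes: int = 40            # planted genes present in the reference set
    n_novel_genes: int = 6       # planted genes absent from the reference
    n_families: int = 18
    n_decoys: int = 30           # reference matures with zero reads
    organs: tuple[str, ...] = ("LL", "RL", "SL", "FL")
    mean_abundance: float = 300.0   # lognormal median of per-gene total reads
    abundance_sigma: float = 1.0
    dispersion: float = 0.25     # NB: var = mu + dispersion * mu^2
    organ_profile_conc: float = 2.0  # Dirichlet concentration of organ shares
    isomir_probs: dict = field(default_factory=lambda: {
        "ext3": 0.10, "trunc3_1": 0.10, "trunc3_2": 0.04,
        "ext5": 0.03, "trunc5_1": 0.03, "sub": 0.05})
    star_fraction: float = 0.12  # expected star/mature read ratio
    contamination_frac: float = 0.30  # fraction of emitted reads that are noise
    length_mode_weights: dict = field(default_factory=lambda: {
        21: 0.20, 24: 0.45, "other": 0.35})
    mature_len: int = 21
    loop_len: tuple[int, int] = (8, 15)
    est_flank: tuple[int, int] = (25, 40)
    n_target_sites: int = 10
    n_wobbled_sites: int = 3     # of the target sites, how many carry 2 G:U wobbles
    n_shifted_genes: int = 5     # genes whose reference entry is a 3'-truncated
    # form of the expressed mature, so the dominant tag is a true isomiR
    n_decoy_ests: int = 10
    n_ncrna: int = 20
    ncrna_len: tuple[int, int] = (80, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.loop_len[0] < 3:
            raise ValueError("hairpin loop must be >= 3 nt")
        p = sum(self.isomir_probs.values())
        if not 0 <= p < 1:
            raise ValueError("isomiR probabilities must sum into [0, 1)")
        w = self.length_mode_weights
        if abs(sum(w.values()) - 1.0) > 1e-9 or any(v < 0 for v in w.values()):
            raise ValueError("length_mode_weights must be a mixture summing to 1")
        if not 0 <= self.contamination_frac < 1:
            raise ValueError("contamination_frac must be in [0, 1)")


@dataclass
class PlantedGene:
    name: str
    family: str
    mature: str
    star: str
    precursor: str               # u2 + mature + loop + star arm
    est_id: str
    precursor_span: tuple[int, int]   # within the EST
    mature_span: tuple[int, int]      # within the EST
    is_novel: bool
    ref_shifted: bool                 # reference holds a truncated form
    organ_means: dict[str, float]     # expected reads per organ (all products)
    variants: dict[str, str]          # variant kind -> sequence

    @property
    def expected_total(self) -> float:
        return sum(self.organ_means.values())


@dataclass
class GroundTruth:
    run_id: str
    config: SimConfig
    genes: list[PlantedGene]
    decoy_names: list[str]
    target_sites: list[tuple[str, str, int, int, int]]
    # (mirna name, est id, start, end, n_wobbles)
    canonical_share: float       # expected fraction of gene reads that are canonical

    def expected_canonical(self, gene: PlantedGene) -> float:
        return gene.expected_total * self.canonical_share


@dataclass
class ReferenceSets:
    matures: list[MatureRef]
    ncrna: list[SequenceRecord]
    ests: list[SequenceRecord]
    truth: GroundTruth


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NT, size=n))


def _make_precursor(rng: np.random.Generator, cfg: SimConfig,
                    ) -> tuple[str, str, str]:
    """Build (mature, star, precursor) with duplex 2-nt 3' overhang geometry.

    precursor = u2 + mature + loop + arm3, where arm3 = revcomp(u2 + mature)
    with 0-2 G:U-compatible substitutions (an imperfect duplex, as in real
    pre-miRNAs); the star is arm3 minus its first two bases plus the two
    bases pairing u2, i.e. the mature's partner shifted by two.
    """
    L = cfg.mature_len
    mature = _rand_seq(rng, L)
    u2 = _rand_seq(rng, 2)
    loop = _rand_seq(rng, int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1)))
    arm5 = u2 + mature
    arm3 = list(revcomp(arm5))
    # G:U-compatible wobbles: opposite a G put U, opposite a U put G
    n_wob = int(rng.integers(0, 3))
    wobblable = [k for k, b in enumerate(reversed(arm5)) if b in "GU"]
    for k in rng.permutation(wobblable)[:n_wob]:
        arm3[k] = "U" if arm5[len(arm5) - 1 - k] == "G" else "G"
    arm3 = "".join(arm3)
    precursor = arm5 + loop + arm3
    star = arm3[2: 2 + L]
    return mature, star, precursor


def simulate_reference_sets(cfg: SimConfig) -> ReferenceSets:
    """Generate the mature reference set, ncRNA set, EST/GSS set and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: list[PlantedGene] = []
    ests: list[SequenceRecord] = []
    seen_matures: set[str] = set()

    n_total = cfg.n_genes + cfg.n_novel_genes
    for g in range(n_total):
        while True:
            mature, star, precursor = _make_precursor(rng, cfg)
            if mature not in seen_matures:
                seen_matures.add(mature)
                break
        is_novel = g >= cfg.n_genes
        ref_shifted = (not is_novel) and g >= cfg.n_genes - cfg.n_shifted_genes
        fam = 9000 + (g % cfg.n_families) if not is_novel else 9500 + g - cfg.n_genes
        letter = chr(ord("a") + g // cfg.n_families)
        name = f"syn-miR{fam}{letter}"
        f5 = _rand_seq(rng, int(rng.integers(*cfg.est_flank)))
        f3 = _rand_seq(rng, int(rng.integers(*cfg.est_flank)))
        est_id = f"EST{g + 1:04d}"
        est = f5 + precursor + f3
        ests.append(SequenceRecord(est_id, est))
        p0 = len(f5)
        m0 = p0 + 2
        # organ expression
        base = float(rng.lognormal(np.log(cfg.mean_abundance), cfg.abundance_sigma))
        shares = rng.dirichlet([cfg.organ_profile_conc] * len(cfg.organs))
        organ_means = {o: base * s for o, s in zip(cfg.organs, shares)}
        variants = _gene_variants(mature, precursor, m0 - p0, rng)
        genes.append(PlantedGene(name, str(fam), mature, star, precursor,
                                 est_id, (p0, p0 + len(precursor)),
                                 (m0, m0 + len(mature)), is_novel, ref_shifted,
                                 organ_means, variants))

    # decoy reference matures: never expressed
    decoys: list[MatureRef] = []
    for d in range(cfg.n_decoys):
        while True:
            seq = _rand_seq(rng, int(rng.integers(20, 23)))
            if seq not in seen_matures:
                seen_matures.add(seq)
                break
        decoys.append(MatureRef(f"dec-miR{9800 + d}", seq))

    matures: list[MatureRef] = []
    for gene in genes:
        if not gene.is_novel:
            # a ref-shifted gene is referenced by its 3'-truncated form, so
            # the expressed full-length mature is a genuine length isomiR
            # that out-expresses its reference (the printed-table situation)
            ref_seq = gene.variants["trunc3_1"] if gene.ref_shifted else gene.mature
            matures.append(MatureRef(gene.name, ref_seq, family=gene.family))
            matures.append(MatureRef(gene.name + "*", gene.star,
                                     family=gene.family, is_star=True))
    matures.extend(decoys)

    # ncRNA set: longer non-miRNA sequences; never equal to a planted mature
    ncrna = []
    for k in range(cfg.n_ncrna):
        seq = _rand_seq(rng, int(rng.integers(*cfg.ncrna_len)))
        ncrna.append(SequenceRecord(f"ncRNA{k + 1:03d}", seq))

    # planted target sites for the first conserved genes
    target_sites: list[tuple[str, str, int, int, int]] = []
    site_genes = [g for g in genes if not g.is_novel][: cfg.n_target_sites]
    for k, gene in enumerate(site_genes):
        site = list(revcomp(gene.mature))
        wob = 0
        if k < cfg.n_wobbled_sites:
            # a G:U wobble sits opposite a mature G or U, i.e. at site
            # positions holding C (-> U) or A (-> G)
            idx = [i for i, b in enumerate(site) if b in "CA"]
            for i in rng.permutation(idx)[:2]:
                site[i] = "U" if site[i] == "C" else "G"
                wob += 1
        site_seq = "".join(site)
        f5 = _rand_seq(rng, int(rng.integers(40, 80)))
        f3 = _rand_seq(rng, int(rng.integers(40, 80)))
        est_id = f"TGT{k + 1:03d}"
        ests.append(SequenceRecord(est_id, f5 + site_seq + f3))
        target_sites.append((gene.name, est_id, len(f5),
                             len(f5) + len(site_seq), wob))

    for k in range(cfg.n_decoy_ests):
        ests.append(SequenceRecord(f"DEC{k + 1:03d}",
                                   _rand_seq(rng, int(rng.integers(100, 200)))))

    canonical_share = 1.0 - sum(cfg.isomir_probs.values())
    truth = GroundTruth(f"sim-{cfg.seed}", cfg, genes,
                        [d.name for d in decoys], target_sites, canonical_share)
    return ReferenceSets(matures, ncrna, ests, truth)


def _gene_variants(mature: str, precursor: str, m_off: int,
                   rng: np.random.Generator) -> dict[str, str]:
    """Templated isomiR sequences for one gene (3'-heterogeneity dominant)."""
    end = m_off + len(mature)
    out = {
        "ext3": mature + precursor[end],         # templated 3' extension
        "trunc3_1": mature[:-1],
        "trunc3_2": mature[:-2],
        "ext5": precursor[m_off - 1] + mature,
        "trunc5_1": mature[1:],
    }
    pos = int(rng.integers(2, len(mature) - 2))
    alt = str(rng.choice([b for b in "ACGU" if b != mature[pos]]))
    out["sub"] = mature[:pos] + alt + mature[pos + 1:]
    return out


def nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
              size: int | None = None):
    """Negative-binomial draws with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    if dispersion <= 0:
        draw = rng.poisson(mean, size)
    else:
        n = 1.0 / dispersion
        p = n / (n + mean)
        draw = rng.negative_binomial(n, p, size)
    return draw


def simulate_libraries(cfg: SimConfig, truth: GroundTruth | None,
                       ) -> tuple[LibrarySet, dict[str, int]]:
    """Emit the four organ libraries as collapsed tags.

    Returns (LibrarySet, bookkeeping library sizes); the sum of tag counts
    per organ equals the bookkeeping size exactly.
    """
    if truth is None:
        raise ValueError("simulate_libraries requires the GroundTruth from "
                         "simulate_reference_sets")
    if truth.run_id != f"sim-{cfg.seed}":
        raise ValueError("GroundTruth was generated under a different config")
    cfg.validate()
    rng = np.random.default_rng((cfg.seed, 1))
    libset = LibrarySet(cfg.organs)
    sizes = {o: 0 for o in cfg.organs}

    kinds = list(cfg.isomir_probs)
    probs = np.array([cfg.isomir_probs[k] for k in kinds])
    canon_p = 1.0 - probs.sum()
    pvec = np.concatenate([[canon_p], probs])

    def emit(seq: str, organ: str, count: int) -> None:
        if count > 0:
            libset.add(Tag(seq, {organ: int(count)}))
            sizes[organ] += int(count)

    for gene in truth.genes:
        for organ in cfg.organs:
            n = int(nb_counts(rng, gene.organ_means[organ], cfg.dispersion))
            if n > 0:
                split = rng.multinomial(n, pvec)
                emit(gene.mature, organ, split[0])
                for kind, c in zip(kinds, split[1:]):
                    emit(gene.variants[kind], organ, c)
            n_star = int(rng.poisson(cfg.star_fraction * n)) if n else 0
            emit(gene.star, organ, n_star)

    # contamination: ncRNA fragments + random oligos, 21/24-nt length modes
    frac = cfg.contamination_frac
    w = cfg.length_mode_weights
    other_lens = [l for l in range(16, 31) if l not in (21, 24)]
    lens = np.array([21, 24] + other_lens)
    lp = np.array([w[21], w[24]] + [w["other"] / len(other_lens)] * len(other_lens))
    ncrna_seqs = getattr(truth, "_ncrna_seqs", None)
    for organ in cfg.organs:
        n_cont = int(round(sizes[organ] * frac / (1.0 - frac)))
        lengths = rng.choice(lens, size=n_cont, p=lp)
        from_nc = rng.random(n_cont) < 0.6 if ncrna_seqs else np.zeros(n_cont, bool)
        for L, use_nc in zip(lengths, from_nc):
            L = int(L)
            if use_nc:
                src = ncrna_seqs[int(rng.integers(len(ncrna_seqs)))]
                start = int(rng.integers(0, len(src) - L + 1))
                seq = src[start: start + L]
            else:
                seq = _rand_seq(rng, L)
            emit(seq, organ, 1)
    return libset, sizes


def attach_ncrna(truth: GroundTruth, ncrna: Sequence[SequenceRecord]) -> None:
    """Let simulate_libraries draw contamination fragments from the ncRNA set."""
    truth._ncrna_seqs = [r.sequence for r in ncrna]


def simulate(cfg: SimConfig) -> tuple[ReferenceSets, LibrarySet, dict[str, int]]:
    """Convenience: reference sets + libraries in one seeded call."""
    refsets = simulate_reference_sets(cfg)
    attach_ncrna(refsets.truth, refsets.ncrna)
    libset, sizes = simulate_libraries(cfg, refsets.truth)
    return refsets, libset, sizes


def emit_fastq_reads(libset: LibrarySet, organ: str, adapter: str,
                     rng: np.random.Generator, read_len: int = 44,
                     quality: int = 38) -> list[SequenceRecord]:
    """Expand one organ's tags into adapter-read-through raw reads."""
    reads = []
    i = 0
    for tag in libset.sorted_tags():
        for _ in range(tag.count(organ)):
            i += 1
            full = tag.sequence + adapter
            if len(full) < read_len:
                full = full + _rand_seq(rng, read_len - len(full))
            reads.append(SequenceRecord(f"{organ}_read{i}", full[:read_len],
                                        [quality] * read_len))
    return reads


def ground_truth_report(truth: GroundTruth, results: dict) -> dict[str, float]:
    """Recovery metrics of a pipeline run against the planted truth.

    ``results`` is the dict produced by the pipeline runner and must carry
    the same ``run_id``.  Metrics use the spec'd qualifying rules: conserved
    recall over planted reference genes with expected canonical reads >= 15;
    novel recovery over novel genes with expected total >= 20.
    """
    if results.get("run_id") != truth.run_id:
        raise ValueError("results were produced from a different run")
    out: dict[str, float] = {}

    kept_seqs = {h.ref.sequence for h in results.get("kept_hits", [])}
    qual = [g for g in truth.genes
            if not g.is_novel and not g.ref_shifted
            and truth.expected_canonical(g) >= 15]
    if qual:
        out["conserved_recall"] = (
            sum(1 for g in qual if g.mature in kept_seqs) / len(qual))
    planted = {g.mature for g in truth.genes} | {g.star for g in truth.genes}
    planted |= {v for g in truth.genes for v in g.variants.values()}
    if kept_seqs:
        out["conserved_precision"] = (
            sum(1 for s in kept_seqs if s in planted) / len(kept_seqs))

    retained_seqs = {c.variant for c in results.get("retained_variants", [])}
    shifted = [g for g in truth.genes
               if g.ref_shifted and truth.expected_canonical(g) >= 15]
    if shifted:
        out["isomir_recovery"] = (
            sum(1 for g in shifted if g.mature in retained_seqs) / len(shifted))

    validated = results.get("validated_precursors", {})
    checked = [g for g in truth.genes if g.name in validated]
    if checked:
        out["precursor_validation_rate"] = (
            sum(1 for g in checked if validated[g.name]) / len(checked))

    calls = results.get("target_calls", [])
    hit_sites = {(c.hybrid.mirna, c.hybrid.target_id) for c in calls if c.passed}
    if truth.target_sites:
        out["target_recall"] = (
            sum(1 for name, est, *_ in truth.target_sites
                if (name, est) in hit_sites) / len(truth.target_sites))

    novel = results.get("novel_candidates", [])
    recovered_ests = {c.precursor.source_id for c in novel}
    qnov = [g for g in truth.genes if g.is_novel and g.expected_total >= 20]
    if qnov:
        out["novel_recovery"] = (
            sum(1 for g in qnov if g.est_id in recovered_ests) / len(qnov))

    retained = results.get("retained_variants", [])
    if retained:
        planted_variants = ({v for g in truth.genes for v in g.variants.values()}
                            | {g.mature for g in truth.genes})
        out["isomir_precision"] = (
            sum(1 for c in retained if c.variant in planted_variants)
            / len(retained))
    return out
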