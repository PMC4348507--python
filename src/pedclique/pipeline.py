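"""Stage orchestration over a working directory.

Each stage reads its upstream artifacts from the working directory, writes
its own, and is deterministic given identical inputs.  Stage order:

    simulate → qc-framework → phase → ibd → cliques → po → impute
    (plus cross-validate and seq-qc side branches)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import clique_index, ibd, imputation, parental_origin, phasing, seq_qc
from .config import PipelineConfig
from .genotype_io import (MISSING, GenotypeMatrix, HaplotypeMatrix, MarkerMap,
                          framework_qc, write_vcf)
from .pedigree import Pedigree, load_pedigree, write_pedigree
from .simulate import SimTruth, gene_drop, make_study, simulate_pedigree

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc-framework", "phase", "ibd", "cliques", "po",
          "impute", "cross-validate", "seq-qc", "merge-ld")


class MissingArtifact(RuntimeError):
    def __init__(self, path: Path, needed_by: str, producer: str):
        super().__init__(f"{needed_by}: missing artifact {path.name}; "
                         f"run the '{producer}' stage first")


class Pipeline:
    def __init__(self, workdir: str | Path, config: PipelineConfig | None = None):
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.config = config or PipelineConfig()

    # -- artifact helpers --------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.workdir / name

    def _require(self, name: str, needed_by: str, producer: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise MissingArtifact(p, needed_by, producer)
        return p

    def _save_markers(self, z: dict, prefix: str, mk: MarkerMap) -> None:
        z[f"{prefix}_chrom"] = mk.chrom
        z[f"{prefix}_bp"] = mk.bp
        z[f"{prefix}_cm"] = mk.cm
        z[f"{prefix}_ref"] = np.asarray(mk.ref, dtype="U8")
        z[f"{prefix}_alt"] = np.asarray(mk.alt, dtype="U8")

    @staticmethod
    def _load_markers(z, prefix: str) -> MarkerMap:
        return MarkerMap(z[f"{prefix}_chrom"], z[f"{prefix}_bp"], z[f"{prefix}_cm"],
                         z[f"{prefix}_ref"].astype(object),
                         z[f"{prefix}_alt"].astype(object))

    # -- stages ------------------------------------------------------------

    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages: {', '.join(STAGES)}")
        getattr(self, "stage_" + stage.replace("-", "_"))()

    def stage_simulate(self) -> None:
        cfg = self.config.sim
        rng = np.random.default_rng(cfg.seed)
        ped = simulate_pedigree(cfg, rng)
        _, truth = gene_drop(ped, cfg, rng)
        study = make_study(ped, truth, cfg, rng)
        write_pedigree(ped, self._path("pedigree.ped"))
        self._path("genotyped.txt").write_text("\n".join(sorted(ped.genotyped)) + "\n")
        z: dict = {"framework_calls": study.framework.calls,
                   "framework_samples": np.asarray(study.framework.sample_ids, dtype="U16"),
                   "seq_calls": study.seq_calls,
                   "sequenced": np.asarray(study.sequenced_ids, dtype="U16"),
                   "truth_labels": truth.labels,
                   "truth_haps": truth.haplotypes,
                   "truth_samples": np.asarray(truth.sample_ids, dtype="U16"),
                   "framework_mask": truth.framework_mask}
        self._save_markers(z, "fw", study.framework.markers)
        self._save_markers(z, "sq", study.seq_variants)
        self._save_markers(z, "union", truth.markers)
        np.savez_compressed(self._path("study.npz"), **z)
        write_vcf(self._path("framework.vcf"), study.framework.markers,
                  study.framework.sample_ids, calls=study.framework.calls)
        log.info("simulated %d genotyped individuals, %d framework markers, "
                 "%d sequence variants", len(study.framework.sample_ids),
                 len(study.framework.markers), len(study.seq_variants))

    def _load_study(self, needed_by: str):
        p = self._require("study.npz", needed_by, "simulate")
        z = np.load(p, allow_pickle=False)
        G = GenotypeMatrix(list(z["framework_samples"]), self._load_markers(z, "fw"),
                           z["framework_calls"])
        ped = load_pedigree(self._path("pedigree.ped"),
                            genotyped=self._path("genotyped.txt").read_text().split())
        truth = SimTruth(list(z["truth_samples"]), self._load_markers(z, "union"),
                         z["framework_mask"], z["truth_labels"], z["truth_haps"])
        return ped, G, truth, z

    def stage_qc_framework(self) -> None:
        ped, G, _, _ = self._load_study("qc-framework")
        c = self.config
        Gq, report = framework_qc(G, ped, max_mendel=c.qc_max_mendel,
                                  hwe_threshold=c.qc_hwe_threshold,
                                  min_call_rate=c.qc_min_call_rate,
                                  min_maf=c.qc_min_maf)
        report.to_frame().to_csv(self._path("qc_report.tsv"), sep="\t", index=False)
        keep = np.flatnonzero(np.array([r == "" for r in report.reason]))
        np.savez_compressed(self._path("qc.npz"), keep=keep)
        log.info("framework QC retained %d / %d markers", len(keep), len(G.markers))

    def stage_phase(self) -> None:
        ped, G, truth, _ = self._load_study("phase")
        zq = np.load(self._require("qc.npz", "phase", "qc-framework"))
        G = G.subset_markers(zq["keep"])
        c = self.config
        H, stats = phasing.phase_cohort(ped, G, eps=c.eps, threshold=c.ibd_threshold,
                                        min_markers=c.min_segment_markers,
                                        surrogate_min_phi=c.surrogate_min_phi,
                                        truth=truth)
        z = {"alleles": H.alleles, "po": H.po,
             "samples": np.asarray(H.sample_ids, dtype="U16"),
             "keep": zq["keep"]}
        self._save_markers(z, "mk", H.markers)
        np.savez_compressed(self._path("haplotypes.npz"), **z)
        self._path("phase_stats.json").write_text(json.dumps({
            "fraction_unphased": stats.fraction_unphased,
            "fraction_concordant": stats.fraction_concordant,
            "fraction_discordant": stats.fraction_discordant}, indent=2) + "\n")
        write_vcf(self._path("phased.vcf"), H.markers, H.sample_ids,
                  calls=G.calls, haplotypes=H.alleles)

    def _load_haps(self, needed_by: str) -> HaplotypeMatrix:
        p = self._require("haplotypes.npz", needed_by, "phase")
        z = np.load(p)
        H = HaplotypeMatrix(list(z["samples"]), self._load_markers(z, "mk"),
                            z["alleles"], z["po"])
        return H

    def stage_ibd(self) -> None:
        ped, _, _, _ = self._load_study("ibd")
        H = self._load_haps("ibd")
        c = self.config
        store = ibd.pairwise_ibd(H, ped, eps=c.eps, threshold=c.ibd_threshold,
                                 min_markers=c.min_segment_markers)
        store.write_tsv(self._path("segments.tsv"))
        log.info("called %d IBD segments over %d haplotype pairs",
                 len(store), store.n_pairs_processed)

    def stage_cliques(self) -> None:
        H = self._load_haps("cliques")
        store = ibd.IBDSegmentStore.read_tsv(
            self._require("segments.tsv", "cliques", "ibd"))
        z = np.load(self._require("study.npz", "cliques", "simulate"))
        # anchors: nearest framework marker of every sequence variant, plus
        # the cross-validation grid
        sq = self._load_markers(z, "sq")
        anchors = {imputation.nearest_framework_marker(H.markers, int(c), int(b))
                   for c, b in zip(sq.chrom, sq.bp)}
        anchors.update(range(0, len(H.markers), self.config.cv_thin))
        D = clique_index.build_dictionary(store, sorted(anchors),
                                          self.config.w_min, self.config.a_min)
        D.write_tsv(self._path("cliques.tsv"))

    def stage_po(self) -> None:
        ped, _, _, _ = self._load_study("po")
        H = self._load_haps("po")
        D = clique_index.CliqueDictionary.read_tsv(
            self._require("cliques.tsv", "po", "cliques"))
        c = self.config
        measures = parental_origin.assign_po_cohort(
            H, D, ped, thin=c.po_thin, informative_cut=c.po_informative_cut,
            assign_cut=c.po_assign_cut)
        with open(self._path("po.tsv"), "w") as fh:
            fh.write("sample\tchrom\torientation\tM\tn_plus\tn_minus\n")
            chroms = H.markers.chromosomes()
            for (s, ch), meas in sorted(measures.items()):
                po = H.po[H.sample_index(s), chroms.index(ch)]
                orient = {H.PO_UNASSIGNED: "unassigned",
                          H.PO_SLOT0_PATERNAL: "slot0-paternal",
                          H.PO_SLOT0_MATERNAL: "slot0-maternal"}[int(po)]
                fh.write(f"{s}\t{ch}\t{orient}\t{meas.M:.4f}\t{meas.n_plus}\t"
                         f"{meas.n_minus}\n")
        z = np.load(self._path("haplotypes.npz"))
        out = {k: z[k] for k in z.files}
        out["alleles"] = H.alleles
        out["po"] = H.po
        np.savez_compressed(self._path("haplotypes.npz"), **out)

    def stage_impute(self) -> None:
        H = self._load_haps("impute")
        D = clique_index.CliqueDictionary.read_tsv(
            self._require("cliques.tsv", "impute", "cliques"))
        z = np.load(self._require("study.npz", "impute", "simulate"))
        sq = self._load_markers(z, "sq")
        sequenced = list(z["sequenced"])
        seq_calls = z["seq_calls"]
        variants = [imputation.VariantRecord(int(sq.chrom[i]), int(sq.bp[i]),
                                             str(sq.ref[i]), str(sq.alt[i]), True,
                                             seq_calls[:, i], id=str(sq.ids[i]))
                    for i in range(len(sq))]
        panel = imputation.impute_all(variants, D, H, sequenced,
                                      self.config.majority_fraction)
        non_seq = [s for s in panel.sample_ids if s not in set(sequenced)]
        summary = {
            "n_variants": len(variants),
            "n_samples": len(non_seq),
            "phasing_rate": panel.phasing_rate,
            "allele_call_rate": panel.allele_call_rate(non_seq),
            "genotype_call_rate": panel.genotype_call_rate(non_seq),
        }
        self._path("impute_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        np.savez_compressed(self._path("imputed.npz"), alleles=panel.alleles,
                            source=panel.source,
                            samples=np.asarray(panel.sample_ids, dtype="U16"))
        geno = panel.genotype_calls()
        write_vcf(self._path("imputed.vcf"), sq, panel.sample_ids,
                  calls=geno.T, haplotypes=np.transpose(panel.alleles, (1, 2, 0)),
                  extra_format={"SRC": panel.source.T})

    def stage_cross_validate(self) -> None:
        H = self._load_haps("cross-validate")
        D = clique_index.CliqueDictionary.read_tsv(
            self._require("cliques.tsv", "cross-validate", "cliques"))
        z = np.load(self._require("study.npz", "cross-validate", "simulate"))
        zq = np.load(self._require("qc.npz", "cross-validate", "qc-framework"))
        G = GenotypeMatrix(list(z["framework_samples"]), self._load_markers(z, "fw"),
                           z["framework_calls"]).subset_markers(zq["keep"])
        rep = imputation.cross_validate(G, D, list(z["sequenced"]),
                                        thin=self.config.cv_thin,
                                        majority_fraction=self.config.majority_fraction)
        self._path("cross_validation.json").write_text(json.dumps({
            "n_markers": rep.n_markers, "n_called": rep.n_called,
            "concordance": rep.concordance, "het_concordance": rep.het_concordance,
        }, indent=2) + "\n")

    def stage_seq_qc(self) -> None:
        ped, _, _, z = self._load_study("seq-qc")
        store = ibd.IBDSegmentStore.read_tsv(
            self._require("segments.tsv", "seq-qc", "ibd"))
        H = self._load_haps("seq-qc")
        sq = self._load_markers(z, "sq")
        sequenced = list(z["sequenced"])
        seq_calls = z["seq_calls"]
        variants = [imputation.VariantRecord(int(sq.chrom[i]), int(sq.bp[i]),
                                             str(sq.ref[i]), str(sq.alt[i]), True,
                                             seq_calls[:, i], id=str(sq.ids[i]))
                    for i in range(len(sq))]
        ibd2 = {}
        for i, a in enumerate(sequenced):
            for b in sequenced[i + 1:]:
                iv = ibd.ibd2_segments(store, (a, b))
                if iv:
                    ibd2[(a, b)] = iv

        def position_of(v):
            return v.chrom, imputation.nearest_framework_marker(H.markers,
                                                                v.chrom, v.bp)

        table = seq_qc.qc_summary_table(variants, ibd2, sequenced, position_of)
        table.to_csv(self._path("seq_qc.tsv"), sep="\t", index=False)

    def stage_merge_ld(self) -> None:
        """Merge externally produced LD-imputation genotype probabilities
        (GEN-format file ``ld_probs.gen`` in the working directory: one
        variant per row, three probabilities per sample, sample order as in
        the imputed panel) into the pedigree calls."""
        z = np.load(self._require("imputed.npz", "merge-ld", "impute"))
        zs = np.load(self._require("study.npz", "merge-ld", "simulate"))
        gen_path = self._path("ld_probs.gen")
        if not gen_path.exists():
            raise MissingArtifact(gen_path, "merge-ld",
                                  "an external LD imputer (GEN output)")
        sq = self._load_markers(zs, "sq")
        samples = list(z["samples"])
        seq_calls = zs["seq_calls"]
        sequenced = list(zs["sequenced"])
        variants = [imputation.VariantRecord(int(sq.chrom[i]), int(sq.bp[i]),
                                             str(sq.ref[i]), str(sq.alt[i]), True,
                                             seq_calls[:, i], id=str(sq.ids[i]))
                    for i in range(len(sq))]
        panel = imputation.ImputedPanel(samples, variants, z["alleles"],
                                        z["source"], sequenced_ids=sequenced)
        key = {(int(c), int(b)): i for i, (c, b) in enumerate(zip(sq.chrom, sq.bp))}
        ld_probs: dict[int, np.ndarray] = {}
        for ln in gen_path.read_text().splitlines():
            f = ln.split()
            vi = key.get((int(f[0]), int(f[2])))
            if vi is None:
                continue
            probs = np.array([float(x) for x in f[5:]]).reshape(-1, 3)
            ld_probs[vi] = probs
        merged = imputation.merge_ld_calls(
            panel, ld_probs, min_prob=self.config.ld_min_prob,
            min_het_concordance=self.config.ld_min_het_concordance,
            min_maf=self.config.ld_min_maf)
        geno = merged.genotype_calls()
        non_seq = [s for s in samples if s not in set(sequenced)]
        nz = [samples.index(s) for s in non_seq]
        summary = {"genotype_call_rate": float((geno[:, nz] != MISSING).mean()),
                   "n_ld_filled": int((merged.source == imputation.SOURCE_LD).sum())}
        self._path("merge_ld_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        write_vcf(self._path("merged.vcf"), sq, samples, calls=geno.T,
                  haplotypes=np.transpose(merged.alleles, (1, 2, 0)),
                  extra_format={"SRC": merged.source.T})

    def run_all(self, stages=STAGES[:7]) -> None:
        for s in stages:
            log.info("=== stage %s ===", s)
            self.run_stage(s)
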