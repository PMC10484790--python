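"""Seeded synthetic fixture generation.

Emits everything the rest of the package consumes — proteins with
planted low-tolerance domains, labeled benchmark tables with controlled
bimodal score distributions, exon-skipping isoform groups with junction
annotations, DMS-like tables with a known monotone relation to planted
effects — plus a ground-truth manifest, all byte-reproducible under a
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .backend import (
    ALPHABET,
    BackendSpec,
    ProteinSequence,
    make_synthetic_backend,
    plant_domain_motifs,
)
from .errors import ValidationError
from .evaluation import DmsAssay, LabeledScoreSet
from .hgvs import ONE_TO_THREE
from .io import write_fasta
from .isoforms import ABSENT, IsoformGroup, VariantIsoformMap
from .scoring import MissenseVariant, direct_llr, score_missense


@dataclass(frozen=True)
class FixtureSpec:
    """Scale and distribution parameters for one fixture bundle."""

    seed: int = 0
    n_proteins: int = 5
    min_length: int = 120
    max_length: int = 400
    domain_length: int = 40
    domain_tolerance: float = 0.02
    n_benign: int = 300
    n_pathogenic: int = 300
    benign_mean: float = -3.0
    benign_sd: float = 1.5
    pathogenic_mean: float = -12.0
    pathogenic_sd: float = 2.0
    n_genes: int = 8
    n_isoform_groups: int = 3
    isoform_length: int = 360
    skip_length: int = 60
    variants_per_group: int = 12
    n_dms_assays: int = 3
    dms_variants_per_assay: int = 40
    dms_noise_sd: float = 0.5

    def __post_init__(self):
        if self.min_length < 2 * self.domain_length:
            raise ValidationError("proteins too short for planted domains")
        if self.skip_length >= self.isoform_length // 2:
            raise ValidationError("skip segment too long for isoform length")
        if self.n_genes < 1 or self.n_proteins < 1:
            raise ValidationError("need at least one gene and one protein")


def _random_protein(rng, length: int, seq_id: str) -> ProteinSequence:
    letters = rng.choice(list(ALPHABET), size=length)
    return ProteinSequence(id=seq_id, residues="".join(letters))


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    proteins: list
    domain_map: dict
    backend: BackendSpec
    benchmark: LabeledScoreSet
    isoform_groups: list
    variant_maps: dict  # gene_id -> list[VariantIsoformMap]
    junctions: dict  # isoform_id -> list of junction aa positions
    dms_assays: list
    dms_predictions: dict
    manifest: dict

    def write(self, outdir) -> None:
        """Write the bundle as plain-text files (deterministic bytes)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        write_fasta(self.proteins, out / "proteins.fasta")
        all_isoforms = [
            iso for group in self.isoform_groups for iso in group.isoforms
        ]
        write_fasta(all_isoforms, out / "isoforms.fasta")

        with open(out / "domains.tsv", "w") as fh:
            fh.write("protein_id\tstart\tend\ttolerance\n")
            for pid in sorted(self.domain_map):
                for start, end, tol in self.domain_map[pid]:
                    fh.write(f"{pid}\t{start}\t{end}\t{tol:.6g}\n")

        bm = self.benchmark
        methods = sorted(bm.scores)
        with open(out / "benchmark.tsv", "w") as fh:
            fh.write("variant_id\tgene_id\tlabel\t" + "\t".join(methods) + "\n")
            for i in range(bm.n):
                label = "pathogenic" if bm.labels[i] else "benign"
                scores = "\t".join(f"{bm.scores[m][i]:.6f}" for m in methods)
                fh.write(f"{bm.variant_ids[i]}\t{bm.gene_ids[i]}\t{label}\t{scores}\n")

        with open(out / "isoform_map.tsv", "w") as fh:
            fh.write("variant_id\tisoform_id\tposition\tref\talt\n")
            for gene_id in sorted(self.variant_maps):
                for vmap in self.variant_maps[gene_id]:
                    for entry in vmap.entries:
                        if entry[1] == ABSENT:
                            fh.write(
                                f"{vmap.variant_id}\t{entry[0]}\t{ABSENT}\t.\t.\n"
                            )
                        else:
                            iso, pos, ref, alt = entry
                            fh.write(f"{vmap.variant_id}\t{iso}\t{pos}\t{ref}\t{alt}\n")

        with open(out / "junctions.tsv", "w") as fh:
            fh.write("isoform_id\tjunction_aa_position\n")
            for iso_id in sorted(self.junctions):
                for pos in self.junctions[iso_id]:
                    fh.write(f"{iso_id}\t{pos}\n")

        with open(out / "dms.tsv", "w") as fh:
            fh.write(
                "gene_id\tassay_id\tvariant_id\tmeasurement\tx_wt"
                "\tcenter_transform\tprediction\n"
            )
            for assay in self.dms_assays:
                preds = self.dms_predictions[assay.assay_id]
                x_wt = "" if assay.x_wt is None else f"{assay.x_wt:.6f}"
                for vid, meas, pred in zip(
                    assay.variant_ids, assay.measurements, preds
                ):
                    fh.write(
                        f"{assay.gene_id}\t{assay.assay_id}\t{vid}\t{meas:.6f}"
                        f"\t{x_wt}\t{assay.center_transform}\t{pred:.6f}\n"
                    )

        with open(out / "backend.json", "w") as fh:
            json.dump(
                {
                    "kind": self.backend.kind,
                    "seed": self.backend.seed,
                    "max_input_length": self.backend.max_input_length,
                    "domain_motifs": [list(m) for m in self.backend.domain_motifs],
                },
                fh,
                indent=2,
                sort_keys=True,
            )

        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def generate_fixtures(spec: FixtureSpec) -> FixtureBundle:
    rng = np.random.default_rng(spec.seed)

    # --- proteins with planted domains -------------------------------------
    proteins = []
    domain_map: dict = {}
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        pid = f"prot{i:03d}"
        proteins.append(_random_protein(rng, length, pid))
        start = int(rng.integers(10, length - spec.domain_length - 5))
        domain_map[pid] = [
            (start, start + spec.domain_length - 1, spec.domain_tolerance)
        ]

    # --- exon-skipping isoform groups --------------------------------------
    isoform_groups = []
    variant_maps: dict = {}
    junctions: dict = {}
    for g in range(spec.n_isoform_groups):
        gene_id = f"isogene{g:02d}"
        primary_id = f"{gene_id}-iso1"
        alt_id = f"{gene_id}-iso2"
        primary = _random_protein(rng, spec.isoform_length, primary_id)

        # Domain in the middle; the skipped segment removes its tail,
        # disrupting the domain in the alternative isoform.
        dom_start = spec.isoform_length // 3
        dom_end = dom_start + spec.domain_length - 1
        cut_start = dom_end - spec.domain_length // 3
        cut_end = cut_start + spec.skip_length - 1
        alt_residues = (
            primary.residues[: cut_start - 1] + primary.residues[cut_end:]
        )
        alt = ProteinSequence(id=alt_id, residues=alt_residues)
        isoform_groups.append(
            IsoformGroup(
                gene_id=gene_id,
                isoforms=(primary, alt),
                primary_isoform_id=primary_id,
            )
        )
        domain_map[primary_id] = [(dom_start, dom_end, spec.domain_tolerance)]
        junctions[primary_id] = []
        junctions[alt_id] = [cut_start - 1]

        # Variants: half inside the intact part of the domain (near the
        # junction, kept in both isoforms), half distal.
        vmaps = []
        near_positions = rng.choice(
            np.arange(dom_start, cut_start), size=spec.variants_per_group // 2,
            replace=False,
        )
        distal_hi = min(dom_start - 2, cut_start - 1)
        distal_positions = rng.choice(
            np.arange(5, distal_hi), size=spec.variants_per_group // 2,
            replace=False,
        )
        for v, pos in enumerate(
            np.concatenate([near_positions, distal_positions])
        ):
            pos = int(pos)
            ref = primary.residues[pos - 1]
            alt_aa = str(rng.choice([a for a in ALPHABET if a != ref]))
            # positions before the cut map identically into the alt isoform
            vmaps.append(
                VariantIsoformMap(
                    variant_id=f"{gene_id}.v{v:02d}",
                    entries=(
                        (primary_id, pos, ref, alt_aa),
                        (alt_id, pos, ref, alt_aa),
                    ),
                )
            )
        variant_maps[gene_id] = vmaps

    # Content-based planting: the skip event breaks the primary's domain
    # substring, so the alternative isoform is automatically tolerant there.
    declaring = proteins + [g.get(g.primary_isoform_id) for g in isoform_groups]
    backend = plant_domain_motifs(
        make_synthetic_backend(spec.seed, domain_spec=domain_map), declaring
    )

    # --- labeled benchmark with planted bimodal scores ----------------------
    n_total = spec.n_benign + spec.n_pathogenic
    labels = np.zeros(n_total, dtype=bool)
    labels[spec.n_benign :] = True
    planted = np.concatenate(
        [
            rng.normal(spec.benign_mean, spec.benign_sd, spec.n_benign),
            rng.normal(spec.pathogenic_mean, spec.pathogenic_sd, spec.n_pathogenic),
        ]
    )
    noisy = planted + rng.normal(0.0, 4.0, n_total)
    gene_ids = tuple(
        f"gene{int(g):02d}" for g in rng.integers(0, spec.n_genes, n_total)
    )
    benchmark = LabeledScoreSet(
        variant_ids=tuple(f"bench.v{i:05d}" for i in range(n_total)),
        labels=labels,
        scores={"plm_llr": planted, "noisy_llr": noisy},
        gene_ids=gene_ids,
    )

    # --- DMS assays keyed to real backend scores ----------------------------
    dms_assays = []
    dms_predictions: dict = {}
    for a in range(spec.n_dms_assays):
        protein = proteins[a % len(proteins)]
        matrix = direct_llr(protein, backend)
        positions = rng.choice(
            np.arange(1, len(protein) + 1),
            size=min(spec.dms_variants_per_assay, len(protein)),
            replace=False,
        )
        variant_ids, effects = [], []
        for pos in positions:
            pos = int(pos)
            ref = protein.residues[pos - 1]
            alt_aa = str(rng.choice([x for x in ALPHABET if x != ref]))
            effect = score_missense(
                matrix,
                MissenseVariant(
                    protein_id=protein.id, position=pos, ref_aa=ref, alt_aa=alt_aa
                ),
            )
            variant_ids.append(
                f"{protein.id}:p.{ONE_TO_THREE[ref]}{pos}{ONE_TO_THREE[alt_aa]}"
            )
            effects.append(effect)
        effects = np.asarray(effects)
        noise = rng.normal(0.0, spec.dms_noise_sd, effects.size)
        center = a == spec.n_dms_assays - 1  # last assay exercises |x - x_wt|
        if center:
            # deviation magnitude decreases with the planted effect; the
            # deviation sign is random, so only |x - x_wt| is informative
            x_wt = 5.0
            magnitude = 6.0 - effects + noise
            signs = rng.choice([-1.0, 1.0], size=effects.size)
            measurements = x_wt + signs * magnitude
        else:
            x_wt = None
            measurements = effects + noise
        dms_assays.append(
            DmsAssay(
                gene_id=protein.id,
                assay_id=f"assay{a:02d}",
                variant_ids=tuple(variant_ids),
                measurements=measurements,
                x_wt=x_wt,
                center_transform=center,
            )
        )
        dms_predictions[f"assay{a:02d}"] = effects

    manifest = {
        "spec": asdict(spec),
        "backend": {"kind": backend.kind, "seed": backend.seed},
        "planted": {
            "benign": {"mean": spec.benign_mean, "sd": spec.benign_sd,
                       "n": spec.n_benign},
            "pathogenic": {"mean": spec.pathogenic_mean, "sd": spec.pathogenic_sd,
                           "n": spec.n_pathogenic},
            "domain_tolerance": spec.domain_tolerance,
        },
        "isoform_groups": {
            group.gene_id: {
                "primary": group.primary_isoform_id,
                "junctions": {
                    iso.id: junctions[iso.id] for iso in group.isoforms
                },
            }
            for group in isoform_groups
        },
    }

    return FixtureBundle(
        spec=spec,
        proteins=proteins,
        domain_map=domain_map,
        backend=backend,
        benchmark=benchmark,
        isoform_groups=isoform_groups,
        variant_maps=variant_maps,
        junctions=junctions,
        dms_assays=dms_assays,
        dms_predictions=dms_predictions,
        manifest=manifest,
    )
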