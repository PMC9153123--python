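"""Forward simulation of annotated coding sequences under the codon model.

The stationary codon-choice distribution is sampled directly (no generational
dynamics): each amino-acid site draws its codon from the family's softmax
probabilities given the gene's phi, with the selection coefficients
sign-flipped at designated heterogeneous-selection sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from codonshift.codon_core import (
    CodonFamilyTable,
    ExpressionVector,
    ParameterSet,
    _STANDARD,
)

__all__ = [
    "LabelSpec",
    "SimulationConfig",
    "SimulatedGene",
    "AnnotatedGenome",
    "random_parameters",
    "simulate_expression",
    "simulate_annotations",
    "flip_selection_sites",
    "simulate_codons",
    "simulate_null_replicates",
    "simulate_genome",
]

#: codons of the two single-codon amino acids, emitted verbatim
_FIXED_CODON = {"M": "ATG", "W": "TGG"}


@dataclass
class LabelSpec:
    """Segment grammar for one structure label.

    ``composition`` maps family ids (one-letter amino acids plus "S4"/"S2",
    optionally "M"/"W") to probabilities.  ``first_k``/``first_k_composition``
    impose a distinct composition at the first k positions of each segment,
    used to reproduce position-dependent amino-acid confounding.
    """

    label: str
    composition: Mapping[str, float]
    mean_segment_length: float = 10.0
    min_segment_length: int = 1
    first_k: int = 0
    first_k_composition: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for comp in (self.composition, self.first_k_composition):
            if comp is not None and abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"label {self.label!r}: composition must sum to 1"
                )
        if self.mean_segment_length < self.min_segment_length:
            raise ValueError("mean_segment_length < min_segment_length")


@dataclass
class SimulationConfig:
    n_genes: int = 100
    mean_length: int = 300  # codons, Poisson-distributed about this mean
    min_length: int = 50
    sdlog: float = 1.0
    labels: Sequence[LabelSpec] = ()
    flip_label: str | None = None
    flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class SimulatedGene:
    gene_id: str
    codons: list[str]
    labels: list[str]
    flipped: np.ndarray
    phi: float

    def __len__(self) -> int:
        return len(self.codons)

    def translate(self) -> str:
        return "".join(_STANDARD.forward_table[c] for c in self.codons)


@dataclass
class AnnotatedGenome:
    """Simulated genes with per-codon labels, flip flags, and truth phi."""

    genes: list[SimulatedGene]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def label_track(self) -> dict[str, list[str]]:
        return {g.gene_id: list(g.labels) for g in self.genes}

    def sequences(self) -> dict[str, list[str]]:
        return {g.gene_id: list(g.codons) for g in self.genes}

    def expression(self) -> ExpressionVector:
        return ExpressionVector(
            [g.gene_id for g in self.genes],
            np.array([g.phi for g in self.genes]),
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n{''.join(g.codons)}\n")

    def write_annotation_tsv(self, path) -> None:
        rows = []
        for g in self.genes:
            for i, (label, flp) in enumerate(zip(g.labels, g.flipped), start=1):
                rows.append((g.gene_id, i, label, int(flp)))
        pd.DataFrame(
            rows, columns=["gene_id", "codon_index", "label", "flipped"]
        ).to_csv(path, sep="\t", index=False)


def random_parameters(
    table: CodonFamilyTable,
    seed: int,
    sd_mutation: float = 0.5,
    sd_selection: float = 0.5,
) -> ParameterSet:
    """Draw a truth parameter set with N(0, sd^2) non-reference entries."""
    rng = np.random.default_rng(seed)
    dm = np.zeros(table.n_codons)
    de = np.zeros(table.n_codons)
    for fam, sl in zip(table.families, table.family_slices().values()):
        ref = sl.start + fam.reference_index
        for j in range(sl.start, sl.stop):
            if j != ref:
                dm[j] = rng.normal(0.0, sd_mutation)
                de[j] = rng.normal(0.0, sd_selection)
    return ParameterSet(table, dm, de)


def simulate_expression(n_genes: int, sdlog: float, seed: int) -> ExpressionVector:
    """Lognormal phi with meanlog = -sdlog^2/2 so that E[phi] = 1."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if sdlog < 0:
        raise ValueError("sdlog must be >= 0")
    rng = np.random.default_rng(seed)
    phi = rng.lognormal(mean=-0.5 * sdlog**2, sigma=sdlog, size=n_genes)
    ids = [f"gene_{i:05d}" for i in range(n_genes)]
    return ExpressionVector(ids, phi)


def _segment_length(spec: LabelSpec, rng: np.random.Generator) -> int:
    # geometric tail above the minimum, matching the configured mean
    excess = spec.mean_segment_length - spec.min_segment_length
    if excess <= 0:
        return spec.min_segment_length
    return spec.min_segment_length + rng.geometric(1.0 / (excess + 1.0)) - 1


def _sample_family_ids(
    comp: Mapping[str, float], n: int, rng: np.random.Generator
) -> list[str]:
    keys = list(comp)
    probs = np.array([comp[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return [keys[i] for i in rng.choice(len(keys), size=n, p=probs)]


def simulate_annotations(
    config: SimulationConfig,
) -> tuple[list[str], list[list[str]], list[list[str]]]:
    """Generate amino-acid templates with alternating labeled segments.

    Returns ``(gene_ids, family_id_sequences, label_sequences)``.  Genes are
    tiled with segments cycling through ``config.labels``; each position's
    family id (amino acid) is drawn from the active label's composition, with
    the optional first-k override applied at segment starts.
    """
    if not config.labels:
        raise ValueError("config.labels must be nonempty")
    rng = np.random.default_rng(config.seed)
    gene_ids, fam_seqs, label_seqs = [], [], []
    for i in range(config.n_genes):
        length = max(config.min_length, int(rng.poisson(config.mean_length)))
        fams: list[str] = []
        labels: list[str] = []
        spec_i = int(rng.integers(len(config.labels)))
        while len(fams) < length:
            spec = config.labels[spec_i % len(config.labels)]
            spec_i += 1
            seg_len = min(_segment_length(spec, rng), length - len(fams))
            head = min(spec.first_k, seg_len) if spec.first_k_composition else 0
            if head:
                fams.extend(_sample_family_ids(spec.first_k_composition, head, rng))
            fams.extend(_sample_family_ids(spec.composition, seg_len - head, rng))
            labels.extend([spec.label] * seg_len)
        gene_ids.append(f"gene_{i:05d}")
        fam_seqs.append(fams)
        label_seqs.append(labels)
    return gene_ids, fam_seqs, label_seqs


def flip_selection_sites(
    labels: Sequence[Sequence[str]],
    flip_fraction: float,
    region_label: str,
    seed: int,
) -> list[np.ndarray]:
    """Choose exactly round(flip_fraction * N) region sites, without replacement.

    ``labels`` is one label sequence per gene; the returned boolean masks are
    aligned with them and are True only at sites carrying ``region_label``.
    Rounding is round-half-to-even.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flat = [
        (g, i)
        for g, lab in enumerate(labels)
        for i, l in enumerate(lab)
        if l == region_label
    ]
    n_flip = round(flip_fraction * len(flat))
    chosen = rng.choice(len(flat), size=n_flip, replace=False) if n_flip else []
    masks = [np.zeros(len(lab), dtype=bool) for lab in labels]
    for k in chosen:
        g, i = flat[k]
        masks[g][i] = True
    return masks


def simulate_codons(
    gene_ids: Sequence[str],
    family_seqs: Sequence[Sequence[str]],
    label_seqs: Sequence[Sequence[str]],
    params: ParameterSet,
    flip_masks: Sequence[np.ndarray],
    phis: ExpressionVector,
    seed: int,
) -> AnnotatedGenome:
    """Draw codons site by site from the model's stationary distribution.

    Sites whose flip mask is set use the negated selection coefficients; the
    amino-acid translation of every gene is preserved by construction.
    """
    table = params.table
    slices = table.family_slices()
    codons_flat = table.codons
    rng = np.random.default_rng(seed)
    if list(gene_ids) != phis.gene_ids:
        raise ValueError("gene_ids must match phis.gene_ids")

    # gather sites per (family, flip-sign) for vectorized sampling
    out_codons: list[list[str | None]] = [[None] * len(s) for s in family_seqs]
    site_index: dict[str, list[tuple[int, int, float]]] = {}
    for g, fams in enumerate(family_seqs):
        phi_g = phis.phi[g]
        mask = flip_masks[g]
        for i, fam_id in enumerate(fams):
            if fam_id in _FIXED_CODON:
                out_codons[g][i] = _FIXED_CODON[fam_id]
                continue
            if fam_id not in slices:
                raise ValueError(f"unknown amino acid / family id {fam_id!r}")
            sign = -1.0 if mask[i] else 1.0
            site_index.setdefault(fam_id, []).append((g, i, sign * phi_g))

    for fam_id, sites in sorted(site_index.items()):
        sl = slices[fam_id]
        dm = params.delta_M[sl]
        de = params.delta_eta[sl]
        signed_phi = np.array([s[2] for s in sites])
        x = -(dm[None, :] + signed_phi[:, None] * de[None, :])
        x -= x.max(axis=1, keepdims=True)
        p = np.exp(x)
        p /= p.sum(axis=1, keepdims=True)
        cdf = np.cumsum(p, axis=1)
        u = rng.random(len(sites))
        draw = (cdf < u[:, None]).sum(axis=1)
        fam_codons = codons_flat[sl]
        for (g, i, _), j in zip(sites, draw):
            out_codons[g][i] = fam_codons[j]

    genes = [
        SimulatedGene(
            gene_id=gid,
            codons=list(out_codons[g]),  # type: ignore[arg-type]
            labels=list(label_seqs[g]),
            flipped=np.asarray(flip_masks[g], dtype=bool),
            phi=float(phis.phi[g]),
        )
        for g, gid in enumerate(gene_ids)
    ]
    return AnnotatedGenome(genes, seed=seed)


def simulate_null_replicates(
    gene_ids: Sequence[str],
    family_seqs: Sequence[Sequence[str]],
    label_seqs: Sequence[Sequence[str]],
    params: ParameterSet,
    phis: ExpressionVector,
    n_replicates: int,
    seed: int,
) -> list[AnnotatedGenome]:
    """Replicate uniform-selection genomes sharing templates and truth phi.

    Replicate seeds are spawned deterministically from the master seed, so
    the set is reproducible while codon draws are independent per replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    empty = [np.zeros(len(s), dtype=bool) for s in family_seqs]
    return [
        simulate_codons(
            gene_ids, family_seqs, label_seqs, params, empty, phis, int(cs)
        )
        for cs in child_seeds
    ]


def simulate_genome(
    config: SimulationConfig, params: ParameterSet
) -> AnnotatedGenome:
    """Full pipeline: expression, annotations, flips, then codon draws."""
    phis = simulate_expression(config.n_genes, config.sdlog, config.seed)
    gene_ids, fam_seqs, label_seqs = simulate_annotations(config)
    if config.flip_label is not None and config.flip_fraction > 0:
        masks = flip_selection_sites(
            label_seqs, config.flip_fraction, config.flip_label, config.seed + 1
        )
    else:
        masks = [np.zeros(len(s), dtype=bool) for s in fam_seqs]
    return simulate_codons(
        gene_ids, fam_seqs, label_seqs, params, masks, phis, config.seed + 2
    )
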