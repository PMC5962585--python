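"""Synthetic log-ratio matrices with planted block/cluster structure.

The generator emulates the statistical shape of a merged multi-study
stress-transcriptome matrix: RNAs fall into planted co-expression blocks
(BTRs), experiments into planted response patterns (PSRs), and each
(block, pattern) pair carries a signed log2 shift.  Within a block, RNAs
share a per-experiment latent factor; with loading λ and noise SD σ the
within-block Pearson correlation from the factor alone is
``r = λ² / (λ² + σ²)``, so any target r maps to ``λ = σ·sqrt(r/(1-r))``.
Planted shifts add further block-structured signal on top.

Within each planted PSR the block-factor values are symmetric about zero
(mirrored pairs), so the true median response of every (block, pattern)
cell equals its planted shift — this is what makes the sign map a
well-defined ground truth.

Companion regulatory structure (annotation terms, TF targets, interaction
edges) is generated with a planted within-block excess over a uniform
background, so the enrichment, TF-sharing and edge-excess analyses are
testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .io import TFTargetMap

__all__ = ["GeneratorConfig", "GroundTruth", "generate_matrix", "generate_regulation"]


def _default_btr_sizes() -> tuple[int, ...]:
    # 20 blocks spanning 10..30 RNAs
    return tuple(int(round(x)) for x in np.linspace(10, 30, 20))


def _default_psr_sizes() -> tuple[int, ...]:
    # 12 patterns spanning 5..15 experiments
    return tuple(int(round(x)) for x in np.linspace(5, 15, 12))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic scenario.

    Defaults are the package's reference conditions: 20 blocks of 10-30
    RNAs plus 100 background RNAs, 12 patterns of 5-15 experiments plus 12
    unassigned experiments, within-block target correlation 0.8, noise SD
    0.3 log2 units, 10% missing cells, shift effect size 1.0 log2 (about
    two-fold) with signs drawn from (-1, 0, +1) at (0.35, 0.30, 0.35) and
    magnitudes jittered by U(0.75, 1.25).  One study per pattern; batch
    shifts off by default.
    """

    btr_sizes: tuple[int, ...] = field(default_factory=_default_btr_sizes)
    psr_sizes: tuple[int, ...] = field(default_factory=_default_psr_sizes)
    n_background_rna: int = 100
    n_background_experiments: int = 12
    target_r: float = 0.8
    loading: float | None = None          # overrides target_r when set
    target_exp_r: float = 0.8             # within-PSR experiment correlation target
    psr_response_sd: float | None = None  # overrides target_exp_r when set
    noise_sd: float = 0.3
    missing_rate: float = 0.10
    batch_sd: float = 0.0
    effect_size: float = 1.0
    sign_probs: tuple[float, float, float] = (0.35, 0.30, 0.35)  # P(-1), P(0), P(+1)
    magnitude_jitter: tuple[float, float] = (0.75, 1.25)
    seed: int = 0
    # regulatory structure
    term_coverage: float = 0.8
    tf_coverage: float = 0.9
    tf_background_rate: float = 0.05
    n_background_tfs: int = 30
    n_background_terms: int = 30
    terms_per_gene: int = 2
    ppi_within_density: float = 0.30
    gi_within_density: float = 0.20
    background_edge_density: float = 0.005

    @property
    def n_rna(self) -> int:
        return sum(self.btr_sizes) + self.n_background_rna

    @property
    def n_experiments(self) -> int:
        return sum(self.psr_sizes) + self.n_background_experiments

    def signature_sd(self) -> float:
        """SD of the background condition-specific response.

        Derived so the expected within-PSR experiment correlation hits
        ``target_exp_r``.  Across RNAs, two experiments of one pattern
        share the planted block shifts and the background signature;
        block factors and noise are experiment-specific.  Solving
        ``r = S / (S + U)`` for the signature variance with
        ``U = f_block·λ² + σ²`` and
        ``S = f_block·E[shift²] + f_bg·ν²`` gives ν below (clipped at 0
        when the shifts alone already exceed the target).
        """
        if self.psr_response_sd is not None:
            return self.psr_response_sd
        if not 0.0 <= self.target_exp_r < 1.0:
            raise ValueError("target_exp_r must be in [0, 1)")
        if self.target_exp_r == 0.0 or self.n_background_rna == 0:
            return 0.0
        f_block = sum(self.btr_sizes) / self.n_rna
        f_bg = self.n_background_rna / self.n_rna
        lo, hi = self.magnitude_jitter
        mag2 = (lo**2 + lo * hi + hi**2) / 3.0       # E[U(lo,hi)^2]
        shift2 = (1.0 - self.sign_probs[1]) * self.effect_size**2 * mag2
        unshared = f_block * self.factor_loading() ** 2 + self.noise_sd**2
        needed = self.target_exp_r / (1.0 - self.target_exp_r) * unshared
        nu2 = (needed - f_block * shift2) / f_bg
        return float(np.sqrt(max(nu2, 0.0)))

    def factor_loading(self) -> float:
        if self.loading is not None:
            return self.loading
        if not 0.0 <= self.target_r < 1.0:
            raise ValueError("target_r must be in [0, 1); use `loading` for r = 1")
        if self.noise_sd == 0.0:
            return 1.0 if self.target_r > 0 else 0.0
        return self.noise_sd * np.sqrt(self.target_r / (1.0 - self.target_r))

    def validate(self) -> "GeneratorConfig":
        if any(s < 2 for s in self.btr_sizes) or any(s < 2 for s in self.psr_sizes):
            raise ValueError("planted block/pattern sizes must be >= 2")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(sum(self.sign_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.sign_probs):
            raise ValueError("sign_probs must be non-negative and sum to 1")
        for frac in (self.term_coverage, self.tf_coverage, self.tf_background_rate,
                     self.ppi_within_density, self.gi_within_density,
                     self.background_edge_density):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("coverage/density fractions must lie in [0, 1]")
        return self


@dataclass
class GroundTruth:
    """Planted structure behind a generated matrix."""

    rna_block: dict[str, str | None]
    experiment_psr: dict[str, str | None]
    sign_map: pd.DataFrame                 # blocks x patterns, values in {-1, 0, +1}
    shift_map: pd.DataFrame                # blocks x patterns, planted log2 shifts
    metadata: pd.DataFrame                 # experiment metadata (study, platform, stress)
    block_term: dict[str, str] = field(default_factory=dict)
    block_tf: dict[str, str] = field(default_factory=dict)
    block_edges: dict[str, set] = field(default_factory=dict)

    def block_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rna, b in self.rna_block.items():
            if b is not None:
                out.setdefault(b, []).append(rna)
        return out

    def psr_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for exp, p in self.experiment_psr.items():
            if p is not None:
                out.setdefault(p, []).append(exp)
        return out


def generate_matrix(config: GeneratorConfig):
    """Generate ``(matrix, truth)`` under the planted-structure model.

    Every RNA of block b in experiment e takes
    ``λ·f_b(e) + shift(b, psr(e)) + batch(study(e), rna) + ε`` with f a
    per-experiment standard-normal factor shared within the block (centred
    within each PSR), ε ~ N(0, noise_sd²); background RNAs are pure noise.
    Cells are masked missing completely at random at ``missing_rate``.
    Fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rna, n_exp = config.n_rna, config.n_experiments
    rna_ids = [f"RNA{i:04d}" for i in range(n_rna)]
    exp_ids = [f"EXP{j:04d}" for j in range(n_exp)]
    block_ids = [f"BTR{k + 1:02d}" for k in range(len(config.btr_sizes))]
    psr_ids = [f"PSR{k + 1:02d}" for k in range(len(config.psr_sizes))]

    rna_block: dict[str, str | None] = {}
    pos = 0
    for bid, size in zip(block_ids, config.btr_sizes):
        for rna in rna_ids[pos : pos + size]:
            rna_block[rna] = bid
        pos += size
    for rna in rna_ids[pos:]:
        rna_block[rna] = None

    experiment_psr: dict[str, str | None] = {}
    pos = 0
    for pid, size in zip(psr_ids, config.psr_sizes):
        for exp in exp_ids[pos : pos + size]:
            experiment_psr[exp] = pid
        pos += size
    for exp in exp_ids[pos:]:
        experiment_psr[exp] = None

    # planted signed shifts per (block, pattern)
    signs = rng.choice(
        [-1, 0, 1], size=(len(block_ids), len(psr_ids)), p=list(config.sign_probs)
    )
    lo, hi = config.magnitude_jitter
    magnitudes = config.effect_size * rng.uniform(lo, hi, size=signs.shape)
    shifts = signs * magnitudes
    sign_map = pd.DataFrame(signs, index=block_ids, columns=psr_ids)
    shift_map = pd.DataFrame(shifts, index=block_ids, columns=psr_ids)

    lam = config.factor_loading()
    psr_of_exp = np.array(
        [psr_ids.index(p) if (p := experiment_psr[e]) is not None else -1 for e in exp_ids]
    )
    # Block factors.  Within each planted pattern the factor values are
    # mirrored +/- pairs (plus a zero when the pattern is odd-sized), in a
    # random order: the factor's distribution over a pattern's experiments
    # is then symmetric about 0, so a block's true median response in the
    # pattern equals its planted shift.  Unassigned experiments draw free
    # standard-normal factors.
    f = rng.standard_normal((len(block_ids), n_exp))
    for k in range(len(psr_ids)):
        cols = np.flatnonzero(psr_of_exp == k)
        if cols.size == 0:
            continue
        half = rng.standard_normal((len(block_ids), cols.size // 2))
        sym = np.concatenate([half, -half], axis=1)
        if cols.size % 2:
            sym = np.concatenate([sym, np.zeros((len(block_ids), 1))], axis=1)
        for b in range(len(block_ids)):
            f[b, cols] = sym[b, rng.permutation(cols.size)]

    block_of_rna = np.array(
        [block_ids.index(b) if (b := rna_block[r]) is not None else -1 for r in rna_ids]
    )
    values = rng.normal(0.0, config.noise_sd, size=(n_rna, n_exp))
    in_block = block_of_rna >= 0
    values[in_block, :] += lam * f[block_of_rna[in_block], :]
    shift_full = shifts[np.clip(block_of_rna, 0, None)][:, np.clip(psr_of_exp, 0, None)]
    planted_cell = (block_of_rna[:, None] >= 0) & (psr_of_exp[None, :] >= 0)
    values += np.where(planted_cell, shift_full, 0.0)

    # condition-specific signature: background RNAs respond per pattern, the
    # response shared by the pattern's experiments (each unassigned
    # experiment gets its own); this is what makes a pattern's experiments
    # correlate beyond the block shifts.
    nu = config.signature_sd()
    if nu > 0 and (~in_block).any():
        bg = np.flatnonzero(~in_block)
        d = rng.normal(0.0, nu, size=(bg.size, len(psr_ids)))
        solo = rng.normal(0.0, nu, size=(bg.size, int((psr_of_exp < 0).sum())))
        solo_col = 0
        for j in range(n_exp):
            if psr_of_exp[j] >= 0:
                values[bg, j] += d[:, psr_of_exp[j]]
            else:
                values[bg, j] += solo[:, solo_col]
                solo_col += 1

    # study structure: one study per pattern, one per unassigned experiment
    studies = []
    extra = 0
    for e in exp_ids:
        p = experiment_psr[e]
        if p is not None:
            studies.append(f"study_{p}")
        else:
            extra += 1
            studies.append(f"study_solo{extra:02d}")
    if config.batch_sd > 0:
        study_ids = sorted(set(studies))
        offsets = {s: rng.normal(0.0, config.batch_sd, size=n_rna) for s in study_ids}
        for j, s in enumerate(studies):
            values[:, j] += offsets[s]

    if config.missing_rate > 0:
        mask = rng.random((n_rna, n_exp)) < config.missing_rate
        values[mask] = np.nan

    matrix = pd.DataFrame(values, index=pd.Index(rna_ids, name="rna"), columns=exp_ids)
    metadata = pd.DataFrame(
        {
            "experiment_id": exp_ids,
            "study_id": studies,
            "platform": "synthetic-two-channel",
            "stress_label": [
                f"stress:{experiment_psr[e] or 'solo'}" for e in exp_ids
            ],
        }
    ).set_index("experiment_id")
    truth = GroundTruth(
        rna_block=rna_block,
        experiment_psr=experiment_psr,
        sign_map=sign_map,
        shift_map=shift_map,
        metadata=metadata,
    )
    return matrix, truth


def generate_regulation(truth: GroundTruth, config: GeneratorConfig):
    """Planted annotation, TF-target and interaction tables for a truth.

    Each planted block gets a dedicated term covering ``term_coverage`` of
    its members, a TF whose targets cover ``tf_coverage`` of the block plus
    uniform background targets, and within-block PPI/GI edges at a planted
    density over a sparse uniform background.  Returns
    ``(AnnotationTable, TFTargetMap, edges DataFrame)``, deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = sorted(truth.rna_block)
    blocks = truth.block_members()

    # annotation: background terms everywhere + one planted term per block
    ann_pairs: list[tuple[str, str]] = []
    bg_terms = [f"TERM_BG{k:02d}" for k in range(config.n_background_terms)]
    for g in genes:
        for t in rng.choice(bg_terms, size=config.terms_per_gene, replace=False):
            ann_pairs.append((g, str(t)))
    for bid, members in blocks.items():
        term = f"TERM_{bid}"
        truth.block_term[bid] = term
        n_cov = int(round(config.term_coverage * len(members)))
        for g in rng.permutation(members)[:n_cov]:
            ann_pairs.append((str(g), term))

    # TF targets: background TFs + one planted TF per block
    tf_pairs: list[tuple[str, str]] = []
    for k in range(config.n_background_tfs):
        tf = f"TF_BG{k:02d}"
        hits = rng.random(len(genes)) < config.tf_background_rate
        for g in np.array(genes)[hits]:
            tf_pairs.append((tf, str(g)))
    for bid, members in blocks.items():
        tf = f"TF_{bid}"
        truth.block_tf[bid] = tf
        n_cov = int(round(config.tf_coverage * len(members)))
        for g in rng.permutation(members)[:n_cov]:
            tf_pairs.append((tf, str(g)))
        bg_hits = rng.random(len(genes)) < config.tf_background_rate
        for g in np.array(genes)[bg_hits]:
            tf_pairs.append((tf, str(g)))

    # interaction edges: planted within-block density over uniform background
    edge_rows: list[dict] = []
    seen: set[frozenset] = set()

    def add_edge(a: str, b: str, kind: str) -> None:
        key = frozenset((a, b, kind))
        if a == b or key in seen:
            return
        seen.add(key)
        edge_rows.append(dict(gene_a=a, gene_b=b, type=kind))

    for kind, density in (("PPI", config.ppi_within_density), ("GI", config.gi_within_density)):
        for bid, members in blocks.items():
            members = list(members)
            planted: set = set()
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < density:
                        add_edge(members[i], members[j], kind)
                        planted.add(frozenset((members[i], members[j])))
            truth.block_edges.setdefault(bid, set()).update(planted)
        n_bg = rng.binomial(len(genes) * (len(genes) - 1) // 2, config.background_edge_density)
        for _ in range(n_bg):
            a, b = rng.choice(genes, size=2, replace=False)
            add_edge(str(a), str(b), kind)

    annotation = AnnotationTable.from_pairs(
        ann_pairs,
        categories={f"TERM_{bid}": "planted" for bid in blocks}
        | {t: "background" for t in bg_terms},
    )
    tfmap = TFTargetMap.from_pairs(tf_pairs)
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "type"])
    return annotation, tfmap, edges
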