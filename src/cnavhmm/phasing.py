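"""Translation of non-phased genotypes into phased genotypes (alt emissions).

A graph may carry an alternative emission symbol on each emit state.  Where
two loci share assay-ambiguous primary symbols (e.g. homologous promoter
variants that the probes cannot separate), the alternative symbols tag each
emission with its locus, resolving the phase.  The translation procedure
mirrors the inference pipeline's final step: simulate a very large set of
path pairs at the posterior-mean transition matrix, group the pairs by their
non-phased genotype, and within each observed genotype's group re-tally the
emissions with the alternative symbols; the relative frequencies of the
resulting phased genotypes are the translation probabilities.

Phased genotypes use the same unordered-sum semantics as primary genotypes:
count vectors over the alternative alphabet, summed over the two haplotypes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeTable
from .graph_model import GraphSpec, TransitionMatrix
from .simulate import DEFAULT_STEP_LIMIT, WalkEngine

__all__ = ["TranslationTable", "PhasingConfigError", "translate"]


class PhasingConfigError(ValueError):
    """The graph's alternative emissions do not support translation."""


@dataclass
class TranslationTable:
    """Per observed genotype: phased genotypes with probabilities.

    ``translations[genotype]`` is a list of ``(phased_genotype, probability)``
    sorted by decreasing probability; probabilities within a genotype sum to
    one.  Observed genotypes matched by fewer than ``min_hits`` simulated
    pairs are listed in ``unmatched`` instead (raise M to resolve them).
    """

    alphabet: tuple[str, ...]
    alt_alphabet: tuple[str, ...]
    translations: dict[tuple[int, ...], list[tuple[tuple[int, ...], float]]]
    draws: int
    seed: int
    min_hits: int
    unmatched: list[tuple[int, ...]]
    hits: dict[tuple[int, ...], int]

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(
            "\t".join(self.alphabet)
            + "\t" + "\t".join(self.alt_alphabet)
            + "\tprobability\n"
        )
        for geno in sorted(self.translations):
            for phased, p in self.translations[geno]:
                buf.write(
                    "\t".join(str(c) for c in geno) + "\t"
                    + "\t".join(str(c) for c in phased)
                    + f"\t{p:.6g}\n"
                )
        return buf.getvalue()


def _alt_to_primary_matrix(g: GraphSpec) -> np.ndarray:
    """(K_alt, K) 0/1 matrix mapping alt symbols back to primary symbols.

    Every emit state must carry an alternative symbol, and each alternative
    symbol must map to a single primary symbol (several states may share a
    primary symbol with *different* alternative symbols — that is the whole
    point — but one alternative symbol may not stand for two primaries).
    """
    sym_idx = {s: i for i, s in enumerate(g.alphabet)}
    alt_idx = {s: i for i, s in enumerate(g.alt_alphabet)}
    mapping: dict[str, str] = {}
    for s in g.states:
        if s.kind != "emit":
            continue
        if s.alt_emit_symbol is None:
            raise PhasingConfigError(
                f"emit state {s.id!r} has no alternative emission symbol; "
                "translation needs one on every emit state"
            )
        prev = mapping.get(s.alt_emit_symbol)
        if prev is not None and prev != s.emit_symbol:
            raise PhasingConfigError(
                f"alternative symbol {s.alt_emit_symbol!r} maps to both "
                f"{prev!r} and {s.emit_symbol!r}"
            )
        mapping[s.alt_emit_symbol] = s.emit_symbol
    m = np.zeros((len(alt_idx), len(sym_idx)), dtype=np.int64)
    for alt, prim in mapping.items():
        m[alt_idx[alt], sym_idx[prim]] = 1
    return m


def translate(
    g: GraphSpec,
    A_bar: TransitionMatrix,
    table: GenotypeTable,
    M: int = 1_000_000,
    seed: int = 0,
    min_hits: int = 100,
    step_limit: int = DEFAULT_STEP_LIMIT,
) -> TranslationTable:
    """Estimate P(phased genotype | non-phased genotype, A_bar) by simulation.

    ``A_bar`` is normally the posterior-mean transition matrix from a fit of
    the same graph on ``table``.  M ordered path pairs are simulated; for
    each distinct observed genotype, the matching pairs' alternative-emission
    sums are tallied into translation probabilities.  Every simulated pair is
    checked to marginalize back to its primary genotype (exact by
    construction of the alt-to-primary map).
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    marg = _alt_to_primary_matrix(g)
    rng = np.random.default_rng(seed)
    engine = WalkEngine(g, A_bar, step_limit)
    res = engine.walk_pairs(M, rng, record_alt=True)
    genos = res["genotypes"]
    phased = res["alt_genotypes"]
    if not np.array_equal(phased @ marg, genos):
        raise AssertionError(
            "a simulated pair's alternative emissions do not marginalize "
            "back to its primary genotype (internal inconsistency)"
        )

    observed = {tuple(int(c) for c in row) for row in table.counts}
    translations: dict = {}
    hits: dict = {}
    unmatched: list = []
    geno_keys = np.array(genos)
    for target in sorted(observed):
        mask = (geno_keys == np.array(target)).all(axis=1)
        n_hit = int(mask.sum())
        hits[target] = n_hit
        if n_hit < min_hits:
            unmatched.append(target)
            continue
        sub = phased[mask]
        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        entries = [
            (tuple(int(c) for c in row), int(c) / n_hit)
            for row, c in zip(uniq, counts)
        ]
        entries.sort(key=lambda e: (-e[1], e[0]))
        translations[target] = entries
    return TranslationTable(
        alphabet=g.alphabet,
        alt_alphabet=g.alt_alphabet,
        translations=translations,
        draws=M,
        seed=seed,
        min_hits=min_hits,
        unmatched=unmatched,
        hits=hits,
    )
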