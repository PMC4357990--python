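"""Synthetic-scenario factory: graphs, ground-truth matrices, data sets.

The package does not ship the original 387-individual MLPA cohort; every
demonstration and test instead runs on data simulated from a canonical graph
with a known ("true") transition matrix.  A :class:`Scenario` bundles graph,
truth and table; regenerating with the same seed reproduces the table
exactly, and scenario seeds are part of the public fixture contract so
downstream checks are stable.

Default truth values are chosen once to resemble the Fc-gamma-receptor
region that motivated the method: haplotype deletion frequencies around
0.1-0.15, duplication probabilities around 0.05-0.1 (most CNVs are gains,
but per-locus both are minority events), intermediate allele frequencies,
and a cohort size of N = 387.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeTable
from .graph_model import GraphSpec, TransitionMatrix, build_canonical
from .simulate import simulate_dataset

__all__ = [
    "Scenario",
    "fcgr_alphabet",
    "fcgr_genes",
    "fcgr_snps",
    "make_scenario",
    "scenario_matrix",
    "SCENARIO_NAMES",
]

# ---------------------------------------------------------------------------
# The Fc-gamma-receptor MLPA panel
# ---------------------------------------------------------------------------

#: the 7 genes of the low-affinity Fc-gamma-receptor MLPA panel
_FCGR_GENES = ("2A", "2B", "2C", "3A", "3B", "HSPA6", "HSPA7")

#: the 9 SNPs the panel distinguishes.  The tri-allelic 3B (HNA-1) system
#: requires three variant positions; only two carry catalog ids in the assay
#: description, the third is listed as unnamed.
_FCGR_SNPS = (
    "rs1801274 (2A H131R)",
    "rs1050501 (2B I232T)",
    "rs183547105 (2C ORF/Stop)",
    "rs396911 (3A F158V)",
    "rs200688856 (3B HNA-1)",
    "rs5030738 (3B HNA-1)",
    "3B HNA-1 third position (unnamed)",
    "rs3219018 (2B/2C promoter C-386G)",
    "rs34701572 (2B/2C promoter A-120T)",
)

#: counting-event symbols of the panel: allele-specific copy counts for the
#: 5 receptor genes, shared (non-phaseable) promoter variants, and the two
#: heat-shock-protein genes counted without allelic variation.
_FCGR_SYMBOLS = (
    "2A_H131", "2A_R131",
    "2B_I232", "2B_T232",
    "2C_ORF", "2C_Stop",
    "3A_F158", "3A_V158",
    "3B_Na1", "3B_Na2", "3B_SH",
    "prom_-386C", "prom_-386G",
    "prom_-120A", "prom_-120T",
    "HSPA6", "HSPA7",
)


def fcgr_alphabet() -> tuple[str, ...]:
    """Ordered emission symbols of the Fc-gamma-receptor MLPA panel."""
    return _FCGR_SYMBOLS


def fcgr_genes() -> tuple[str, ...]:
    """The 7 genes whose copy numbers the panel determines."""
    return _FCGR_GENES


def fcgr_snps() -> tuple[str, ...]:
    """The 9 SNPs whose allelic variants the panel distinguishes."""
    return _FCGR_SNPS


# ---------------------------------------------------------------------------
# Ground-truth transition matrices per scenario
# ---------------------------------------------------------------------------

def _matrix_with_rows(
    g: GraphSpec, rows: dict[str, dict[str, float]]
) -> TransitionMatrix:
    """Full matrix from per-state target->probability rows.

    States without a row get a uniform distribution over their out-edges;
    specified rows must cover their probability mass exactly (unmentioned
    out-edges of a specified state get probability 0).
    """
    probs = np.zeros(len(g.edges))
    for s in g.states:
        out = g.out_edges(s.id)
        if not out:
            continue
        if s.id in rows:
            row = rows[s.id]
            targets = {b for _, (_, b) in out}
            unknown = set(row) - targets
            if unknown:
                raise ValueError(
                    f"state {s.id!r}: no edge to {sorted(unknown)}"
                )
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"state {s.id!r}: row probabilities sum to {total}, not 1"
                )
            for i, (_, b) in out:
                probs[i] = row.get(b, 0.0)
        else:
            for i, _ in out:
                probs[i] = 1.0 / len(out)
    tm = TransitionMatrix(g, probs)
    tm.validate(tol=1e-9)
    return tm


def _hwe_matrix(g: GraphSpec, alleles, p: float = 0.5) -> TransitionMatrix:
    return _matrix_with_rows(
        g, {"choose": {alleles[0]: p, alleles[1]: 1.0 - p}}
    )


def _cnav_matrix(
    g: GraphSpec,
    alleles,
    loss: float = 0.15,
    gain: float = 0.1,
    allele_probs=None,
    loss_branch: bool = True,
    gain_loop: bool = True,
) -> TransitionMatrix:
    if allele_probs is None:
        allele_probs = [1.0 / len(alleles)] * len(alleles)
    rows: dict[str, dict[str, float]] = {
        "choose": dict(zip(alleles, allele_probs)),
    }
    if loss_branch:
        rows["in"] = {"del": loss, "choose": 1.0 - loss}
    if gain_loop:
        rows["post"] = {"out": 1.0 - gain, "gain": gain}
    return _matrix_with_rows(g, rows)


def _loh_matrix(
    g: GraphSpec, alleles, loss: float = 0.15, loh: float = 0.1,
    allele_probs=None,
) -> TransitionMatrix:
    if allele_probs is None:
        allele_probs = [1.0 / len(alleles)] * len(alleles)
    rows = {
        "in": {"del": loss, "choose": 1.0 - loss},
        "choose": dict(zip(alleles, allele_probs)),
    }
    for a in alleles:
        rows[a] = {a: loh, "out": 1.0 - loh}
    return _matrix_with_rows(g, rows)


def _first_order_matrix(
    g: GraphSpec, alleles, loss: float = 0.15, exit_prob: float = 0.6,
    self_repeat: float = 0.1,
) -> TransitionMatrix:
    rows = {
        "in": {"del": loss, "choose": 1.0 - loss},
        "choose": {a: 1.0 / len(alleles) for a in alleles},
    }
    spread = (1.0 - exit_prob - self_repeat) / (len(alleles) - 1)
    for a in alleles:
        row = {b: spread for b in alleles if b != a}
        row[a] = self_repeat
        row["out"] = exit_prob
        rows[a] = row
    return _matrix_with_rows(g, rows)


def _tandem_matrix(
    g: GraphSpec, alleles, tandem, loss: float = 0.1, gain: float = 0.05,
    tandem_prob: float = 0.15, repeat_prob: float = 0.05,
    allele_probs=None,
) -> TransitionMatrix:
    if allele_probs is None:
        share = (1.0 - tandem_prob) / len(alleles)
        allele_probs = [share] * len(alleles)
    t1 = f"tandem:{tandem[0]}+{tandem[1]}.1"
    rows: dict[str, dict[str, float]] = {
        "in": {"del": loss, "choose": 1.0 - loss},
        "choose": {**dict(zip(alleles, allele_probs)), t1: tandem_prob},
        "post": {"out": 1.0 - gain, "gain": gain},
    }
    repeat_allele = next(
        (s.id for s in g.states if (s.id, s.id) in g.edge_index), None
    )
    if repeat_allele is not None:
        rows[repeat_allele] = {repeat_allele: repeat_prob,
                               "post": 1.0 - repeat_prob}
    return _matrix_with_rows(g, rows)


def _two_locus_matrix(
    g: GraphSpec,
    promoter_symbols=("promC", "promG"),
    locus1_alleles=("I232", "T232"),
    locus2_alleles=("ORF", "Stop"),
    prefixes=("b", "c"),
    b_prom_c: float = 0.55,
    c_prom_c: float = 0.5,
    linkage_b=(0.9, 0.2),
    linkage_c=(0.85, 0.1),
    loss: float = 0.15,
    gain: float = 0.1,
    loops: bool = True,
) -> TransitionMatrix:
    """Truth for the two-locus phasing scenario.

    ``linkage_b[0]`` is P(first coding allele | first promoter allele) at
    locus 1, ``linkage_b[1]`` the same given the second promoter allele;
    ``linkage_b=(1, 0)`` is complete linkage (coding allele determined by
    promoter allele), which makes the phasing translation deterministic.
    """
    p1, p2 = prefixes
    pC, pG = promoter_symbols
    a1, b1 = locus1_alleles
    a2, b2 = locus2_alleles
    rows: dict[str, dict[str, float]] = {
        f"{p1}_in": {f"{p1}_{pC}": b_prom_c, f"{p1}_{pG}": 1.0 - b_prom_c},
        f"{p1}_{pC}": {f"{p1}_{a1}": linkage_b[0],
                       f"{p1}_{b1}": 1.0 - linkage_b[0]},
        f"{p1}_{pG}": {f"{p1}_{a1}": linkage_b[1],
                       f"{p1}_{b1}": 1.0 - linkage_b[1]},
        f"{p2}_choose": {f"{p2}_{pC}": c_prom_c, f"{p2}_{pG}": 1.0 - c_prom_c},
        f"{p2}_{pC}": {f"{p2}_{a2}": linkage_c[0],
                       f"{p2}_{b2}": 1.0 - linkage_c[0]},
        f"{p2}_{pG}": {f"{p2}_{a2}": linkage_c[1],
                       f"{p2}_{b2}": 1.0 - linkage_c[1]},
    }
    if loops:
        rows[f"{p2}_in"] = {f"{p2}_del": loss, f"{p2}_choose": 1.0 - loss}
        rows[f"{p2}_post"] = {f"{p2}_out": 1.0 - gain, f"{p2}_gain": gain}
    return _matrix_with_rows(g, rows)


def independent_cnv_matrix(
    g: GraphSpec, genes, del_prob: float = 0.15, gain_prob: float = 0.1
) -> TransitionMatrix:
    """Truth on the fully connected graph with *independent* gene CNV.

    Realizes, on the fully connected topology, a canonical-order chain with
    skips: each gene is present on a haplotype independently with
    probability 1 - del_prob and, when present, carries a geometric number
    of copies with continuation probability gain_prob.  Backward edges get
    probability 0, so the data generated carry no order dependence beyond
    the arbitrary canonical labeling — the symmetric, multimodal case.
    """
    m = len(genes)
    d = [del_prob] * m
    rows: dict[str, dict[str, float]] = {}

    def onward(i: int, scale: float) -> dict[str, float]:
        # from position i (before gene i), distribute scale over genes i..m-1, end
        row: dict[str, float] = {}
        acc = scale
        for j in range(i, m):
            row[genes[j]] = acc * (1.0 - d[j])
            acc *= d[j]
        row["end"] = acc
        return row

    rows["start"] = onward(0, 1.0)
    for i, gene in enumerate(genes):
        row = {gene: gain_prob}
        row.update(
            {k: v for k, v in onward(i + 1, 1.0 - gain_prob).items()}
        )
        rows[gene] = row
    return _matrix_with_rows(g, rows)


def block_linked_cnv_matrix(
    g: GraphSpec, genes, del_free: float = 0.15, gain_free: float = 0.1,
    del_block: float = 0.25, gain_block: float = 0.15,
) -> TransitionMatrix:
    """Truth with the last two genes gained/lost as one block.

    The first gene varies independently; the last two always co-occur (they
    are deleted together with probability ``del_block`` and duplicated as a
    unit with probability ``gain_block``), so their copy counts are equal on
    every haplotype — maximal copy-number linkage.
    """
    if len(genes) != 3:
        raise ValueError("block_linked_cnv_matrix expects exactly 3 genes")
    a, b, c = genes
    rows = {
        "start": {
            a: 1.0 - del_free,
            b: del_free * (1.0 - del_block),
            "end": del_free * del_block,
        },
        a: {
            a: gain_free,
            b: (1.0 - gain_free) * (1.0 - del_block),
            "end": (1.0 - gain_free) * del_block,
        },
        b: {c: 1.0},
        c: {b: gain_block, "end": 1.0 - gain_block},
    }
    return _matrix_with_rows(g, rows)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A named study condition: graph, true matrix, simulated table, seed."""

    name: str
    graph: GraphSpec
    truth: TransitionMatrix
    table: GenotypeTable
    N: int
    seed: int
    description: str
    params: dict = field(default_factory=dict)

    def regenerate(self) -> GenotypeTable:
        """Re-simulate the table; bit-identical to ``self.table``."""
        return simulate_dataset(self.graph, self.truth, self.N, self.seed)


SCENARIO_NAMES = (
    "hwe_biallelic",
    "cnav_multiallele",
    "cnav_loh",
    "first_order_dependency",
    "tandem_allele",
    "two_locus_phasing",
    "fully_connected_block",
)


def scenario_matrix(name: str, g: GraphSpec, params: dict) -> TransitionMatrix:
    """Ground-truth matrix for a named scenario (params override defaults)."""
    if name == "hwe_biallelic":
        alleles = params.get("alleles", ("A", "B"))
        return _hwe_matrix(g, alleles, p=params.get("p", 0.5))
    if name == "cnav_multiallele":
        alleles = params.get("alleles", ("A", "B"))
        return _cnav_matrix(
            g, alleles,
            loss=params.get("loss", 0.15),
            gain=params.get("gain", 0.1),
            allele_probs=params.get("allele_probs"),
            loss_branch=params.get("loss_branch", True),
            gain_loop=params.get("gain_loop", True),
        )
    if name == "cnav_loh":
        alleles = params.get("alleles", ("A", "B"))
        return _loh_matrix(
            g, alleles, loss=params.get("loss", 0.15),
            loh=params.get("loh", 0.1),
            allele_probs=params.get("allele_probs"),
        )
    if name == "first_order_dependency":
        alleles = params.get("alleles", ("Na1", "Na2", "SH"))
        return _first_order_matrix(
            g, alleles, loss=params.get("loss", 0.15),
            exit_prob=params.get("exit_prob", 0.6),
            self_repeat=params.get("self_repeat", 0.1),
        )
    if name == "tandem_allele":
        alleles = params.get("alleles", ("Na1", "Na2", "SH"))
        tandem = params.get("tandem", ("SH", "Na1"))
        return _tandem_matrix(
            g, alleles, tandem,
            loss=params.get("loss", 0.1),
            gain=params.get("gain", 0.05),
            tandem_prob=params.get("tandem_prob", 0.15),
            repeat_prob=params.get("repeat_prob", 0.05),
            allele_probs=params.get("allele_probs"),
        )
    if name == "two_locus_phasing":
        return _two_locus_matrix(
            g,
            b_prom_c=params.get("b_prom_c", 0.55),
            c_prom_c=params.get("c_prom_c", 0.5),
            linkage_b=params.get("linkage_b", (0.9, 0.2)),
            linkage_c=params.get("linkage_c", (0.85, 0.1)),
            loss=params.get("loss", 0.15),
            gain=params.get("gain", 0.1),
            loops=params.get("loops", True),
        )
    if name == "fully_connected_block":
        genes = params.get("genes", ("3A", "2C", "3B"))
        if params.get("linkage", "independent") == "block":
            return block_linked_cnv_matrix(
                g, genes,
                del_free=params.get("del_free", 0.15),
                gain_free=params.get("gain_free", 0.1),
                del_block=params.get("del_block", 0.25),
                gain_block=params.get("gain_block", 0.15),
            )
        return independent_cnv_matrix(
            g, genes,
            del_prob=params.get("del_prob", 0.15),
            gain_prob=params.get("gain_prob", 0.1),
        )
    raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")


_GRAPH_OPTION_KEYS = {
    "hwe_biallelic": ("alleles",),
    "cnav_multiallele": ("alleles", "loss_branch", "gain_loop"),
    "cnav_loh": ("alleles",),
    "first_order_dependency": ("alleles",),
    "tandem_allele": ("alleles", "tandem"),
    "two_locus_phasing": ("loops",),
    "fully_connected_block": ("genes",),
}


def make_scenario(
    name: str,
    overrides: dict | None = None,
    N: int = 387,
    seed: int = 0,
) -> Scenario:
    """Build a ready-to-use scenario: graph, truth matrix, simulated table.

    ``overrides`` adjusts the scenario's true transition probabilities and
    (where applicable) graph options — e.g. ``{"p": 0.3}`` for the allele
    frequency of ``hwe_biallelic``, or ``{"linkage": "block"}`` for the
    block-linked fully connected case.  The default N mirrors the
    387-individual cohort scale of the motivating study.
    """
    params = dict(overrides or {})
    graph_opts = {
        k: params[k] for k in _GRAPH_OPTION_KEYS.get(name, ()) if k in params
    }
    g = build_canonical(name, **graph_opts)
    truth = scenario_matrix(name, g, params)
    table = simulate_dataset(g, truth, N, seed)
    return Scenario(
        name=name, graph=g, truth=truth, table=table, N=N, seed=seed,
        description=f"synthetic {name} scenario (N={N}, seed={seed})",
        params=params,
    )
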