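"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one external resource at desk scale:

* yeast genetic-interaction tables with a planted set of strong negative
  interactions (epsilon < -0.2, P < 0.05), a controllable fraction of
  reciprocal duplicates, and P drawn as a decreasing function of |epsilon|
  plus noise;
* InParanoid-style ortholog clusters with a known one-to-one core plus
  one-to-many / many-to-one / many-to-many distractors, and consistent
  gene<->protein bridges;
* paired tumor/normal expression: per-gene log-normal baselines, tumor =
  normal x 2^(planted log2 effect) x multiplicative log-normal noise, zeros
  sprinkled missing-at-random;
* drug screens with marker expression from a continuous distribution and a
  planted downward IC50 shift in the marker-low group.

Every generator is deterministic given its seed and returns the planted
truth alongside the data, so downstream recovery is checkable exactly. The
``simulate_bundle`` convenience wires the generators together into a
consistent end-to-end input set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_de import PairedExpressionData
from .network_build import GeneticInteractionRecord
from .ortholog_map import IdBridge, OrthologCluster

__all__ = [
    "SimulationTruth",
    "SimulationBundle",
    "simulate_yeast_gi",
    "simulate_ortholog_resources",
    "simulate_paired_expression",
    "simulate_drug_screen",
    "simulate_bundle",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for recovery tests.

    ``one_to_one_pairs`` are gene-level yeast->human mappings;
    ``strong_yeast_pairs`` are the canonical (sorted) yeast gene pairs that
    pass both interaction cutoffs; ``true_sl_edges`` are the human gene
    pairs expected to survive filtering plus translation;
    ``down_gene_ids`` carry the planted log2 expression effect.
    """

    one_to_one_pairs: frozenset[tuple[str, str]] = frozenset()
    strong_yeast_pairs: frozenset[tuple[str, str]] = frozenset()
    true_sl_edges: frozenset[tuple[str, str]] = frozenset()
    down_gene_ids: frozenset[str] = frozenset()
    planted_log2fc: float = 0.0
    sensitive_drug_shift: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.planted_log2fc):
            raise ValueError("planted_log2fc must be finite")
        human_images = {h for _, h in self.one_to_one_pairs}
        if human_images:
            for a, b in self.true_sl_edges:
                if a not in human_images or b not in human_images:
                    raise ValueError(
                        f"true SL edge ({a}, {b}) has an endpoint outside the "
                        "one-to-one image"
                    )

    def merged(self, other: "SimulationTruth") -> "SimulationTruth":
        return SimulationTruth(
            one_to_one_pairs=self.one_to_one_pairs | other.one_to_one_pairs,
            strong_yeast_pairs=self.strong_yeast_pairs | other.strong_yeast_pairs,
            true_sl_edges=self.true_sl_edges | other.true_sl_edges,
            down_gene_ids=self.down_gene_ids | other.down_gene_ids,
            planted_log2fc=self.planted_log2fc or other.planted_log2fc,
            sensitive_drug_shift=self.sensitive_drug_shift or other.sensitive_drug_shift,
        )

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("one_to_one_pairs", "strong_yeast_pairs", "true_sl_edges"):
            d[key] = sorted(list(p) for p in d[key])
        d["down_gene_ids"] = sorted(d["down_gene_ids"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            one_to_one_pairs=frozenset(tuple(p) for p in d["one_to_one_pairs"]),
            strong_yeast_pairs=frozenset(tuple(p) for p in d["strong_yeast_pairs"]),
            true_sl_edges=frozenset(tuple(p) for p in d["true_sl_edges"]),
            down_gene_ids=frozenset(d["down_gene_ids"]),
            planted_log2fc=d["planted_log2fc"],
            sensitive_drug_shift=d["sensitive_drug_shift"],
        )


def _yeast_gene(i: int) -> str:
    return f"Y{i:05d}W"


def _yeast_protein(i: int) -> str:
    return f"PY{i:05d}"


def _human_gene(i: int) -> str:
    return f"HGN{i:04d}"


def _human_protein(i: int) -> str:
    return f"QH{i:05d}"


def _unrank_pair(k: int, n: int) -> tuple[int, int]:
    """k-th unordered pair (i < j) of range(n), row-major."""
    i = 0
    remaining = k
    row = n - 1
    while remaining >= row:
        remaining -= row
        i += 1
        row -= 1
    return i, i + 1 + remaining


def simulate_yeast_gi(
    n_genes: int,
    n_records: int,
    frac_strong: float,
    frac_reciprocal: float,
    seed: int,
    gene_names: Optional[Sequence[str]] = None,
) -> tuple[list[GeneticInteractionRecord], SimulationTruth]:
    """Simulate a screen table with planted strong negative interactions.

    ``n_records`` unique unordered gene pairs are drawn; a fraction
    ``frac_strong`` of them get epsilon < -0.2 and P < 0.05 (the true set),
    and ``frac_reciprocal`` of those strong pairs additionally appear as a
    swapped (reciprocal) record, so the table can contain more rows than
    ``n_records``. Every non-strong record fails at least one cutoff. P is a
    decreasing function of |epsilon| with multiplicative noise.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not (0 <= frac_strong <= 1 and 0 <= frac_reciprocal <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    max_pairs = n_genes * (n_genes - 1) // 2
    if n_records > max_pairs:
        raise ValueError(
            f"n_records={n_records} exceeds the {max_pairs} distinct pairs of "
            f"{n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = list(gene_names) if gene_names is not None else [
        _yeast_gene(i) for i in range(n_genes)
    ]
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    pair_ids = rng.choice(max_pairs, size=n_records, replace=False)
    n_strong = int(round(frac_strong * n_records))

    def strong_eps_p(size: int) -> tuple[np.ndarray, np.ndarray]:
        eps = -rng.uniform(0.25, 1.0, size=size)
        p = np.minimum(
            0.049, 0.05 * np.exp(-4.0 * (-eps - 0.25)) * rng.uniform(0.2, 1.0, size=size)
        )
        return eps, p

    records: list[GeneticInteractionRecord] = []
    strong_pairs: set[tuple[str, str]] = set()
    eps_s, p_s = strong_eps_p(n_strong)
    for k in range(n_strong):
        i, j = _unrank_pair(int(pair_ids[k]), n_genes)
        a, b = genes[i], genes[j]
        records.append(GeneticInteractionRecord(a, b, float(eps_s[k]), float(p_s[k])))
        strong_pairs.add((min(a, b), max(a, b)))

    for k in range(n_strong, n_records):
        i, j = _unrank_pair(int(pair_ids[k]), n_genes)
        a, b = genes[i], genes[j]
        if rng.random() < 0.5:
            eps = float(rng.uniform(-0.19, 0.4))  # too weak
            p = float(rng.uniform(1e-6, 1.0))
        else:
            eps = float(-rng.uniform(0.25, 1.0))  # strong but not significant
            p = float(rng.uniform(0.05, 1.0))
        records.append(GeneticInteractionRecord(a, b, eps, p))

    n_recip = int(round(frac_reciprocal * n_strong))
    eps_r, p_r = strong_eps_p(n_recip)
    for k in range(n_recip):
        orig = records[k]
        records.append(
            GeneticInteractionRecord(
                orig.array_gene, orig.query_gene, float(eps_r[k]), float(p_r[k])
            )
        )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = SimulationTruth(strong_yeast_pairs=frozenset(strong_pairs))
    return records, truth


_DISTRACTOR_SHAPES = ((1, 2), (2, 1), (2, 2), (1, 3), (3, 1))


def simulate_ortholog_resources(
    n_yeast: int,
    n_human: int,
    frac_one_to_one: float,
    seed: int,
) -> tuple[list[OrthologCluster], IdBridge, SimulationTruth]:
    """Simulate ortholog clusters with a planted one-to-one core.

    ``frac_one_to_one`` of min(n_yeast, n_human) genes form single-member
    clusters on both sides (the recoverable core); remaining genes are
    packed into multi-member distractor clusters cycling through
    one-to-many, many-to-one and many-to-many shapes. Bridges map every
    yeast gene to a unique protein and every human protein to a unique gene.
    """
    if n_yeast < 1 or n_human < 1:
        raise ValueError("counts must be at least 1")
    if not (0 <= frac_one_to_one <= 1):
        raise ValueError("frac_one_to_one must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_core = int(round(frac_one_to_one * min(n_yeast, n_human)))

    clusters: list[OrthologCluster] = []
    truth_pairs: set[tuple[str, str]] = set()
    for i in range(n_core):
        clusters.append(
            OrthologCluster(
                cluster_id=f"OC{len(clusters):05d}",
                yeast_members=((_yeast_protein(i), 1.0),),
                human_members=((_human_protein(i), 1.0),),
            )
        )
        truth_pairs.add((_yeast_gene(i), _human_gene(i)))

    yi, hi = n_core, n_core
    shape_idx = 0
    while True:
        ny, nh = _DISTRACTOR_SHAPES[shape_idx % len(_DISTRACTOR_SHAPES)]
        shape_idx += 1
        if yi + ny > n_yeast or hi + nh > n_human:
            break
        yeast_members = tuple(
            (_yeast_protein(yi + k), 1.0 if k == 0 else float(rng.uniform(0.3, 1.0)))
            for k in range(ny)
        )
        human_members = tuple(
            (_human_protein(hi + k), 1.0 if k == 0 else float(rng.uniform(0.3, 1.0)))
            for k in range(nh)
        )
        clusters.append(
            OrthologCluster(
                cluster_id=f"OC{len(clusters):05d}",
                yeast_members=yeast_members,
                human_members=human_members,
            )
        )
        yi += ny
        hi += nh

    bridge = IdBridge(
        yeast_gene_to_protein={_yeast_gene(i): _yeast_protein(i) for i in range(n_yeast)},
        human_protein_to_gene={_human_protein(i): _human_gene(i) for i in range(n_human)},
    )
    truth = SimulationTruth(one_to_one_pairs=frozenset(truth_pairs))
    return clusters, bridge, truth


def simulate_paired_expression(
    n_genes: int,
    n_patients: int,
    n_down: int,
    log2fc: float,
    sigma: float,
    zero_rate: float,
    seed: int,
    gene_names: Optional[Sequence[str]] = None,
    down_genes: Optional[Sequence[str]] = None,
) -> tuple[PairedExpressionData, SimulationTruth]:
    """Simulate aligned tumor/normal matrices with a planted log2 effect.

    Normal values are log-normal per gene; tumor values multiply the paired
    normal value by 2^(log2fc) for the ``n_down`` planted genes (effect 0
    elsewhere) and by multiplicative log-normal noise of scale ``sigma``
    (log2 units) everywhere. Zeros are sprinkled uniformly at random at
    ``zero_rate`` per cell in each matrix independently.
    """
    if n_patients < 2:
        raise ValueError("paired design requires at least 2 patients")
    if n_down > n_genes:
        raise ValueError("n_down cannot exceed n_genes")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0 <= zero_rate <= 1):
        raise ValueError("zero_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(gene_names) if gene_names is not None else [
        f"GENE{i:04d}" for i in range(n_genes)
    ]
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    patients = [f"TCGA-SY-{i:04d}" for i in range(n_patients)]

    if down_genes is not None:
        down = list(down_genes)
        if len(down) != n_down or not set(down) <= set(genes):
            raise ValueError("down_genes must be n_down members of the gene universe")
    else:
        down = list(rng.choice(genes, size=n_down, replace=False))
    effect = np.zeros(n_genes)
    down_set = set(down)
    for i, g in enumerate(genes):
        if g in down_set:
            effect[i] = log2fc

    # Per-gene log-normal baseline around a few hundred normalized counts.
    mu = rng.normal(np.log(300.0), 1.0, size=n_genes)
    normal = np.exp(mu[:, None] + rng.normal(0.0, 0.7, size=(n_genes, n_patients)))
    noise = rng.normal(0.0, sigma, size=(n_genes, n_patients))
    tumor = normal * np.exp2(effect[:, None] + noise)

    if zero_rate > 0:
        tumor = tumor.copy()
        normal = normal.copy()
        tumor[rng.random((n_genes, n_patients)) < zero_rate] = 0.0
        normal[rng.random((n_genes, n_patients)) < zero_rate] = 0.0

    data = PairedExpressionData(
        tumor=pd.DataFrame(tumor, index=genes, columns=patients),
        normal=pd.DataFrame(normal, index=genes, columns=patients),
    )
    truth = SimulationTruth(
        down_gene_ids=frozenset(down_set), planted_log2fc=float(log2fc)
    )
    return data, truth


DEFAULT_DOSES = (0.01, 0.1, 1.0, 10.0, 100.0)


def simulate_drug_screen(
    n_lines: int,
    shift: float,
    seed: int,
    drug: str = "DRUG1",
    doses: Sequence[float] = DEFAULT_DOSES,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate one drug's screen with a planted IC50 shift in marker-low lines.

    Marker expression is Gaussian (location 5, scale 1); IC50s (natural-log
    uM scale) are Gaussian (location 3, scale 1) and shifted *down* by
    ``shift`` for lines at or below the mean marker expression (more
    sensitive). Survival percentages per dose follow a logistic curve around
    each line's IC50. Columns: cell_line, drug, ic50, marker_expr, plus one
    ``surv_<dose>`` column per concentration.
    """
    if n_lines < 4:
        raise ValueError("need at least 4 cell lines")
    rng = np.random.default_rng(seed)
    lines = [f"CL{i:04d}" for i in range(n_lines)]
    marker = rng.normal(5.0, 1.0, size=n_lines)
    ic50 = rng.normal(3.0, 1.0, size=n_lines)
    low_mask = marker <= marker.mean()
    ic50 = np.where(low_mask, ic50 - shift, ic50)

    table = pd.DataFrame(
        {
            "cell_line": lines,
            "drug": drug,
            "ic50": ic50,
            "marker_expr": marker,
        }
    )
    for dose in doses:
        surv = 100.0 / (1.0 + np.exp(1.2 * (np.log(dose) - ic50)))
        surv = np.clip(surv + rng.normal(0.0, 2.0, size=n_lines), 0.0, 100.0)
        table[f"surv_{dose:g}"] = surv
    truth = SimulationTruth(sensitive_drug_shift=float(shift))
    return table, truth


@dataclass(frozen=True)
class SimulationBundle:
    """All pipeline inputs generated jointly, with one merged truth."""

    gi_records: list[GeneticInteractionRecord]
    clusters: list[OrthologCluster]
    bridge: IdBridge
    expression: PairedExpressionData
    drug_screen: pd.DataFrame
    truth: SimulationTruth


def simulate_bundle(
    seed: int,
    n_yeast: int = 120,
    n_human: int = 120,
    frac_one_to_one: float = 0.6,
    n_gi_records: int = 400,
    frac_strong: float = 0.5,
    frac_reciprocal: float = 0.3,
    n_expr_genes: int = 200,
    n_patients: int = 100,
    n_down: int = 10,
    log2fc: float = -2.0,
    sigma: float = 0.2,
    zero_rate: float = 0.002,
    n_lines: int = 200,
    drug_shift: float = 3.0,
) -> SimulationBundle:
    """Generate one consistent input set for an end-to-end pipeline run.

    The yeast GI table is drawn over the ortholog simulation's yeast gene
    universe, so the planted strong pairs whose both endpoints lie in the
    one-to-one core define the expected humanized edge set exactly.
    Expression genes include all simulated human symbols (padded with
    fillers up to ``n_expr_genes``), and planted down genes are taken
    preferentially from nodes of the expected human network so the disease
    subnetwork is non-empty. The default per-cell zero rate of 0.002 makes
    roughly a third of genes fail the all-patients non-zero filter at 100
    patients, the proportion seen in real paired tumor/normal cohorts.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)

    clusters, bridge, orth_truth = simulate_ortholog_resources(
        n_yeast, n_human, frac_one_to_one, int(sub_seeds[0])
    )
    yeast_genes = sorted(bridge.yeast_gene_to_protein)
    gi_records, gi_truth = simulate_yeast_gi(
        len(yeast_genes), n_gi_records, frac_strong, frac_reciprocal,
        int(sub_seeds[1]), gene_names=yeast_genes,
    )

    gene_map = dict(orth_truth.one_to_one_pairs)
    true_edges = set()
    for a, b in gi_truth.strong_yeast_pairs:
        ha, hb = gene_map.get(a), gene_map.get(b)
        if ha is not None and hb is not None and ha != hb:
            true_edges.add((min(ha, hb), max(ha, hb)))

    human_genes = sorted({_human_gene(i) for i in range(n_human)})
    fillers = [f"GENE{i:04d}" for i in range(max(0, n_expr_genes - len(human_genes)))]
    expr_genes = human_genes + fillers
    network_nodes = sorted({g for e in true_edges for g in e})
    n_down_net = min(n_down // 2 + 1, len(network_nodes), n_down)
    down_net = list(rng.choice(network_nodes, size=n_down_net, replace=False)) if n_down_net else []
    pool = [g for g in expr_genes if g not in set(down_net)]
    down_rest = list(rng.choice(pool, size=n_down - n_down_net, replace=False))
    down = down_net + down_rest

    expression, expr_truth = simulate_paired_expression(
        len(expr_genes), n_patients, n_down, log2fc, sigma, zero_rate,
        int(sub_seeds[2]), gene_names=expr_genes, down_genes=down,
    )
    drug_screen, drug_truth = simulate_drug_screen(
        n_lines, drug_shift, int(sub_seeds[3])
    )

    truth = SimulationTruth(
        one_to_one_pairs=orth_truth.one_to_one_pairs,
        strong_yeast_pairs=gi_truth.strong_yeast_pairs,
        true_sl_edges=frozenset(true_edges),
        down_gene_ids=expr_truth.down_gene_ids,
        planted_log2fc=float(log2fc),
        sensitive_drug_shift=float(drug_shift),
    )
    return SimulationBundle(
        gi_records=gi_records,
        clusters=clusters,
        bridge=bridge,
        expression=expression,
        drug_screen=drug_screen,
        truth=truth,
    )
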