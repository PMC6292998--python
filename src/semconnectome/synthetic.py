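"""Download-free fixtures: the printed connectivity x differential-
expression table records, and a generator for fully wired synthetic
knowledge bases with planted statistical structure.

The generator emulates the study conditions of an averaged multimodal
connectome joined with region-pair differential expression: a parcellation
of regions with MNI coordinates, a two-level anatomical ontology (region
terms with sub-structure children under one root), symmetric structural
([0, 1]) and functional ([-1, 1]) connectivity matrices, DEG counts
between *sub-structure* terms only (so the cross-modal join needs the is-a
expansion), a hub region of maximal weighted degree, a target negative
rank association between functional connectivity and DEG count, and one
"putamen-like" exception region that is strongly structurally connected
yet highly differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import atlas_ontology as ao
from .connectome import ConnectionRecord, import_connectivity_matrix
from .kgcore import DataError, KnowledgeBase
from .transcriptome import import_deg

__all__ = [
    "SynthConfig",
    "generate_kb",
    "paper_tables_fixture",
    "generate_expression_fixture",
    "SYNTH_ATLAS",
    "SYNTH_ONTOLOGY",
    "SYNTH_ROOT",
]

SYNTH_ATLAS = "synth_atlas"
SYNTH_ONTOLOGY = "synth_ontology"
SYNTH_ROOT = "T_root"

#: DEG counts of non-exception region pairs are clamped to this ceiling, so
#: the exception region is the only source of counts above the "highly
#: differentially expressed" threshold (strictly > 200).
DEG_CEILING = 200
EXCEPTION_DEG_RANGE = (400, 900)


# ---------------------------------------------------------------------------
# In-print table fixture
# ---------------------------------------------------------------------------

# (origin, target, normalized structural, functional, DEG average), in the
# printed row order; duplicates are genuine (several coordinate pairs share
# the same region labels).
_TABLE1 = [
    ("left putamen", "left parahippocampal posterior", 0.163502106, 0.020203011, 687.5),
    ("left putamen", "left planum temporale", 0.18985185, -0.01262453, 625),
    ("left frontal pole", "left putamen", 0.28089338, 0.15076964, 927),
    ("left frontal pole", "left putamen", 0.268176361, 0.13167174, 927),
    ("left frontal medial", "left putamen", 0.110934828, 0.094022519, 790),
    ("left frontal pole", "left putamen", 0.478702548, 0.21312926, 927),
    ("left frontal pole", "left putamen", 0.10229685, 0.11504351, 927),
    ("left frontal orbital", "left putamen", 0.355902746, 0.32012312, 726),
    ("left frontal pole", "left putamen", 0.200164537, 0.1399255, 927),
    ("left frontal orbital", "left putamen", 0.23406272, 0.19123371, 726),
    ("left frontal pole", "left putamen", 0.187038633, 0.17440578, 927),
    ("right putamen", "right heschl's", 0.251257875, 0.049333889, 695),
    ("right putamen", "right parahippocampal posterior", 0.240377155, 0.027959258, 687.5),
    ("right putamen", "right planum polare", 0.361161921, 0.1971855, 655),
    ("right frontal pole", "right putamen", 0.135257294, 0.2283248, 927),
    ("right frontal pole", "right putamen", 0.342326336, 0.16207665, 927),
    ("left frontal medial", "right putamen", 0.103986254, 0.14005883, 790),
    ("right frontal pole", "right putamen", 0.174086567, 0.13810447, 927),
    ("right frontal orbital", "right putamen", 0.275009861, 0.24960994, 726),
    ("right frontal pole", "right putamen", 0.289418731, 0.11346083, 927),
    ("right temporal pole", "right putamen", 0.290537649, 0.24174925, 806.5),
    ("right frontal pole", "right putamen", 0.145893171, 0.13850855, 927),
    ("right frontal pole", "right putamen", 0.61517917, 0.27000022, 927),
    ("right frontal pole", "right putamen", 0.175577644, 0.10383046, 927),
    ("right temporal pole", "right putamen", 0.117579801, 0.083963864, 806.5),
]

_TABLE2 = [
    ("right lingual", "left occipital fusiform", 0.264136489, 0.73615919, 271.6666667),
    ("left lingual", "left occipital fusiform", 0.22772869, 0.60275624, 271.6666667),
    ("right lingual", "left parahippocampal posterior", 0.143716534, 0.50098513, 251.5),
    ("left lingual", "left parahippocampal posterior", 0.30761773, 0.55396672, 251.5),
    ("right lingual", "right occipital fusiform", 0.177391911, 0.51224682, 271.6666667),
    ("right lingual", "right occipital fusiform", 0.235064117, 0.68679426, 271.6666667),
    ("left lingual", "right occipital fusiform", 0.02712589, 0.61838067, 271.6666667),
    ("right lingual", "right parahippocampal posterior", 0.33430536, 0.51577434, 251.5),
]

_TABLE3 = [
    ("left superior parietal lobule", "left superior parietal lobule",
     0.558669936, 0.71112541, 3),
    ("left superior parietal lobule", "left superior parietal lobule",
     0.558669936, 0.71112541, 3),
    ("right cingulate anterior", "right cingulate anterior",
     0.605500596, 0.53997424, 0),
    ("right juxtapositional lobule", "right cingulate anterior",
     0.596213811, 0.71527726, 7.75),
    ("right cingulate anterior", "right cingulate anterior",
     0.605500596, 0.53997424, 0),
    ("right juxtapositional lobule", "right cingulate posterior",
     0.521552114, 0.55794716, 0.5),
    ("right cingulate anterior", "right cingulate posterior",
     0.631735262, 0.58602299, 1.5),
    ("right superior parietal lobule", "right superior parietal lobule",
     0.695758645, 0.68872082, 3),
    ("right superior parietal lobule", "right superior parietal lobule",
     0.695758645, 0.68872082, 3),
]


def paper_tables_fixture(table: Optional[int] = None) -> list[ConnectionRecord]:
    """The 25 + 8 + 9 = 42 published connection records (putamen-centred
    high-DEG connections; strong functional connections with high DEG; and
    strong connections with near-identical expression), with the printed
    values and duplicates preserved.  ``table`` in {1, 2, 3} selects one of
    the three published tables; default is all records in order."""
    tables = {1: (_TABLE1,), 2: (_TABLE2,), 3: (_TABLE3,),
              None: (_TABLE1, _TABLE2, _TABLE3)}
    if table not in tables:
        raise DataError(f"table must be 1, 2, 3 or None, got {table!r}")
    records = []
    for tbl in tables[table]:
        for origin, target, struct, func, deg in tbl:
            records.append(ConnectionRecord(
                origin=origin, target=target, structural=struct,
                functional=func, deg_average=float(deg), n_subpairs=1))
    return records


# ---------------------------------------------------------------------------
# Synthetic knowledge-base generator
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Study conditions for the synthetic connectome x transcriptome
    knowledge base.

    Defaults give 21 regions with one coordinate each, hence 210 region
    pairs in the fully connected graph — the scale at which the planted
    rank association is recovered — two sub-structures per region carrying
    the DEG links, a hub at region 0 and the exception region at index 1
    connecting strongly to ``n_exception_targets`` regions.
    """

    n_regions: int = 21
    coords_per_region: int = 1
    seed: int = 0
    hub_region: int = 0
    exception_region: int = 1
    deg_conn_association: float = -0.6
    n_substructures: int = 2
    n_exception_targets: int = 6
    structural_method: str = "DTI"
    functional_method: str = "rs-fMRI"

    def validate(self) -> None:
        if self.n_regions < 3:
            raise DataError("n_regions must be at least 3")
        if not (0 <= self.hub_region < self.n_regions):
            raise DataError("hub_region index out of range")
        if not (0 <= self.exception_region < self.n_regions):
            raise DataError("exception_region index out of range")
        if self.hub_region == self.exception_region:
            raise DataError("hub and exception regions must differ")
        if not -1.0 <= self.deg_conn_association <= 0.0:
            raise DataError("deg_conn_association must lie in [-1, 0]")
        if self.coords_per_region < 1 or self.n_substructures < 1:
            raise DataError("coords_per_region and n_substructures must be >= 1")


def _region_name(r: int) -> str:
    return f"region {r:02d}"


def _exception_pairs(cfg: SynthConfig) -> set[tuple[int, int]]:
    """The region pairs carrying the planted putamen-style exception."""
    targets = [r for r in range(cfg.n_regions)
               if r not in (cfg.hub_region, cfg.exception_region)]
    return {tuple(sorted((cfg.exception_region, t)))
            for t in targets[: cfg.n_exception_targets]}


def _structural_matrix(cfg: SynthConfig, rng: np.random.Generator,
                       region_of: Sequence[int]) -> np.ndarray:
    n = len(region_of)
    s = rng.uniform(0.01, 0.55, size=(n, n))
    s = np.triu(s, 1)
    s = s + s.T
    exc_pairs = _exception_pairs(cfg)
    for i in range(n):
        for j in range(i + 1, n):
            if tuple(sorted((region_of[i], region_of[j]))) in exc_pairs:
                s[i, j] = rng.uniform(0.3, 0.7)
                s[j, i] = s[i, j]
    # hub row last so its degree dominates everything else
    for i in range(n):
        if region_of[i] == cfg.hub_region:
            for j in range(n):
                if region_of[j] != cfg.hub_region:
                    s[i, j] = rng.uniform(0.75, 0.95)
                    s[j, i] = s[i, j]
    np.fill_diagonal(s, 0.0)
    return s


def _functional_matrix(cfg: SynthConfig, s: np.ndarray,
                       rng: np.random.Generator,
                       region_of: Sequence[int]) -> np.ndarray:
    """Functional connectivity as a noisy monotone transform of structural
    connectivity: f = -0.25 + 1.3 s + N(0, 0.15), clipped to [-1, 1], with
    the floor raised above zero where s > 0.4 so that strong tracts only
    show positive activity correlations.  The exception region breaks the
    transform: its planted connections stay weakly correlated (putamen-like
    high fiber density with near-zero activity correlation)."""
    noise = rng.normal(0.0, 0.15, size=s.shape)
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    f = np.clip(-0.25 + 1.3 * s + noise, -1.0, 1.0)
    f[s > 0.4] = np.clip(f[s > 0.4], 0.02, 1.0)
    exc_pairs = _exception_pairs(cfg)
    n = len(region_of)
    for i in range(n):
        for j in range(i + 1, n):
            if tuple(sorted((region_of[i], region_of[j]))) in exc_pairs:
                f[i, j] = rng.uniform(0.0, 0.33)
                f[j, i] = f[i, j]
    np.fill_diagonal(f, 0.0)
    return f


def _deg_counts(cfg: SynthConfig, rng: np.random.Generator,
                func_by_pair: dict[tuple[int, int], float]) -> pd.DataFrame:
    """Draw DEG counts per sub-structure pair via a Gaussian copula against
    the functional connectivity rank, targeting a Spearman correlation of
    ``deg_conn_association``; counts are rounded log-normal, clamped for
    non-exception pairs and overridden upward for exception pairs."""
    pairs = sorted(func_by_pair)
    f = np.array([func_by_pair[p] for p in pairs])
    ranks = stats.rankdata(f)
    z_f = stats.norm.ppf((ranks - 0.5) / len(ranks))
    # latent correlation giving the target Spearman rho exactly under the
    # Gaussian copula: rho_latent = 2 sin(pi * rho_s / 6)
    rho = 2.0 * np.sin(np.pi * cfg.deg_conn_association / 6.0)
    z_d = rho * z_f + np.sqrt(max(0.0, 1.0 - rho ** 2)) * \
        rng.standard_normal(len(pairs))

    exc_pairs = _exception_pairs(cfg)

    rows = []
    for (r, q), z in zip(pairs, z_d):
        is_exception = tuple(sorted((r, q))) in exc_pairs
        for sa in range(cfg.n_substructures):
            for sb in range(cfg.n_substructures):
                if is_exception:
                    count = int(rng.integers(*EXCEPTION_DEG_RANGE))
                else:
                    count = int(round(np.exp(3.5 + 0.8 * (z + 0.15 *
                                                          rng.standard_normal()))))
                    count = min(count, DEG_CEILING)
                rows.append((f"T_r{r:02d}_s{sa}", f"T_r{q:02d}_s{sb}", count))
    return pd.DataFrame(rows, columns=["structure_a", "structure_b", "deg_count"])


def generate_kb(config: Optional[SynthConfig] = None) -> KnowledgeBase:
    """Build a complete synthetic knowledge base: coordinates, atlas,
    two-level ontology, mappings, both connectivity modalities and DEG
    links.  Deterministic per seed."""
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    kb = KnowledgeBase()

    n = cfg.n_regions * cfg.coords_per_region
    region_of = [i // cfg.coords_per_region for i in range(n)]
    labels = [_region_name(region_of[i]) for i in range(n)]
    coord_ids = [f"c{i:03d} r{region_of[i]:02d}" for i in range(n)]
    xyz = rng.uniform([-70, -105, -60], [70, 70, 75], size=(n, 3))
    coordinates = pd.DataFrame(xyz, columns=["x", "y", "z"])

    # atlas + ontology + mapping chain
    atlas_table = pd.DataFrame({
        "entry_id": [f"A{r:02d}" for r in range(cfg.n_regions)],
        "label": [_region_name(r) for r in range(cfg.n_regions)],
    })
    ao.load_flat_atlas(kb, SYNTH_ATLAS, atlas_table)

    term_rows = [(SYNTH_ROOT, "synthetic brain")]
    edge_rows = []
    for r in range(cfg.n_regions):
        rt = f"T_r{r:02d}"
        term_rows.append((rt, _region_name(r)))
        edge_rows.append((rt, SYNTH_ROOT))
        for s in range(cfg.n_substructures):
            st = f"T_r{r:02d}_s{s}"
            term_rows.append((st, f"{_region_name(r)} sub {s}"))
            edge_rows.append((st, rt))
    ao.load_ontology(
        kb, SYNTH_ONTOLOGY,
        pd.DataFrame(term_rows, columns=["term_id", "name"]),
        pd.DataFrame(edge_rows, columns=["child_id", "parent_id"]))

    mapping = pd.DataFrame({
        "atlas": SYNTH_ATLAS,
        "entry_id": [f"A{r:02d}" for r in range(cfg.n_regions)],
        "structure_name": [_region_name(r) for r in range(cfg.n_regions)],
        "ontology": SYNTH_ONTOLOGY,
        "term_id": [f"T_r{r:02d}" for r in range(cfg.n_regions)],
    })

    # connectivity (structural first, functional re-uses the relations)
    s = _structural_matrix(cfg, rng, region_of)
    f = _functional_matrix(cfg, s, rng, region_of)
    import_connectivity_matrix(
        kb, s, labels, coordinates, cfg.structural_method,
        "normalized fiber density", experiment_name="synthetic DTI avg",
        coordinate_ids=coord_ids)
    import_connectivity_matrix(
        kb, f, labels, coordinates, cfg.functional_method,
        "normalized correlation value", experiment_name="synthetic fc avg",
        coordinate_ids=coord_ids)

    ao.parcellate_coordinates(
        kb, coord_ids,
        pd.DataFrame({"coordinate_id": coord_ids,
                      "entry_id": [f"A{r:02d}" for r in region_of]}),
        SYNTH_ATLAS)
    ao.register_brain_mapping(kb, mapping)

    # differential expression between sub-structure terms, driven by the
    # mean functional connectivity of each region pair
    func_by_pair: dict[tuple[int, int], list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = sorted((region_of[i], region_of[j]))
            if ri == rj:
                continue
            func_by_pair.setdefault((ri, rj), []).append(f[i, j])
    mean_func = {p: float(np.mean(v)) for p, v in func_by_pair.items()}
    import_deg(kb, _deg_counts(cfg, rng, mean_func), ontology=SYNTH_ONTOLOGY)
    return kb


# ---------------------------------------------------------------------------
# Expression fixture
# ---------------------------------------------------------------------------

def generate_expression_fixture(
    kb: KnowledgeBase,
    hotspot_structure: str,
    genes: Sequence[str],
    seed: int = 0,
    n_locations: int = 10,
    probes_per_gene: int = 2,
    donor: str = "donor1",
) -> pd.DataFrame:
    """A probe-level expression table with a planted expression hotspot.

    The listed genes get values above 8 with PACall 1 at the hotspot
    structure and sub-threshold or invalid signals elsewhere (including
    one above-8/PACall-0 decoy per gene), so a localized-expression query
    returns the hotspot only.  Locations other than the hotspot are drawn
    from the knowledge base's brain structures.  Deterministic per seed.
    """
    if not kb.has_instance(ao.STRUCTURE_TYPE, hotspot_structure):
        raise DataError(f"hotspot structure {hotspot_structure!r} not in kb")
    rng = np.random.default_rng(seed)
    others = [s.identifier for s in kb.instances_of(ao.STRUCTURE_TYPE)
              if s.identifier != hotspot_structure][: n_locations - 1]
    rows = []
    for gene in genes:
        for p in range(probes_per_gene):
            probe = f"{gene}_p{p}"
            rows.append((donor, hotspot_structure, probe, gene,
                         float(rng.uniform(8.5, 11.0)), 1))
            for k, loc in enumerate(others):
                if p == 0 and k == 0:
                    # decoy: strong signal not significantly above noise
                    rows.append((donor, loc, probe, gene,
                                 float(rng.uniform(8.2, 9.0)), 0))
                else:
                    rows.append((donor, loc, probe, gene,
                                 float(rng.uniform(4.0, 7.9)),
                                 int(rng.integers(0, 2))))
    return pd.DataFrame(
        rows, columns=["donor", "structure_id", "probe_id", "gene_symbol",
                       "expression", "pacall"])
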