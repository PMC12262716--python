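"""consentropy: consensus clustering and entropy diagnostics for spatially
aware clustering of spatial omics data.

Rather than crowning a single best spatial-domain detection method, this
package aggregates the cluster labelings produced by many methods and
configurations into a consensus labeling, and maps where the methods agree
and disagree: smoothness entropy scores the spatial coherence of each base
clustering, cross-method entropy highlights the observations on which the
ensemble is uncertain, and three consensus algorithms (K-modes, latent
class analysis, weighted Jensen–Shannon co-association) synthesize the
final partition.
"""

__version__ = "0.1.0"

from .consensus import (
    ConsensusResult,
    KModesConsensus,
    LCAConsensus,
    LcaModel,
    WeightedJSDConsensus,
    bernoulli_jsd,
    kmodes_consensus,
    lca_consensus,
    resolution_search,
    weighted_consensus,
)
from .evaluation import SweepGrid, leave_one_out, run_consensus, sweep_grid
from .labelings import (
    LabelingCollection,
    SpatialLabeling,
    build_collection,
    read_labeling,
    write_labeling,
)
from .metrics import (
    AgreementMatrix,
    EntropyField,
    NeighborGraph,
    align_labelings,
    border_mask,
    build_knn_graph,
    cross_method_entropy,
    pairwise_agreement,
    shannon_entropy,
    smoothness_entropy,
)
from .selection import (
    SelectionReport,
    concordance_block,
    filter_imbalanced,
    select_smoothest,
)
from .synthetic import (
    NoiseSpec,
    SyntheticTissue,
    default_noise_specs,
    generate_collection,
    granularity_specs,
    generate_tissue,
    perturb_labeling,
)

__all__ = [
    "__version__",
    "SpatialLabeling",
    "LabelingCollection",
    "read_labeling",
    "write_labeling",
    "build_collection",
    "NeighborGraph",
    "EntropyField",
    "AgreementMatrix",
    "shannon_entropy",
    "build_knn_graph",
    "smoothness_entropy",
    "border_mask",
    "pairwise_agreement",
    "align_labelings",
    "cross_method_entropy",
    "SelectionReport",
    "filter_imbalanced",
    "select_smoothest",
    "concordance_block",
    "ConsensusResult",
    "LcaModel",
    "KModesConsensus",
    "LCAConsensus",
    "WeightedJSDConsensus",
    "bernoulli_jsd",
    "resolution_search",
    "kmodes_consensus",
    "lca_consensus",
    "weighted_consensus",
    "SweepGrid",
    "leave_one_out",
    "sweep_grid",
    "run_consensus",
    "SyntheticTissue",
    "NoiseSpec",
    "generate_tissue",
    "perturb_labeling",
    "generate_collection",
    "default_noise_specs",
    "granularity_specs",
]
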