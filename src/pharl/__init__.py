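"""PHARL: physics-aware alignment representation learning for fall-motion windows.

Weakly supervised contrastive representation learning in which simulation-
derived contact outcomes (Supported / Trunk / Head) reshape the relation
structure of a trajectory-contrast objective — masking cross-trajectory
contact windows out of contact anchors' denominators and attracting exact
class matches across trajectories — so that an ordinal severity structure
emerges in the embedding space without any ordinal supervision.
"""

__version__ = "0.1.0"

from .config import (CLASSES, ORDINAL, EncoderConfig, EvalConfig, LabelConfig,
                     LossConfig, RelationConfig, RunConfig, SimConfig,
                     TrainConfig, load_run_config, substream)
from .evaluation import (evaluate, neighborhood_consistency, pcr, poa_macro,
                         project, severity_axis, spearman_kendall)
from .io import (ContactDescriptor, EmbeddingTable, GroundTruth, Manifest,
                 Window, read_descriptors, read_embeddings, read_labels,
                 read_manifest, write_descriptors, write_embeddings,
                 write_labels, write_manifest)
from .labeling import (ImpulseSet, PhysicsLabel, assign_label,
                       build_impulse_set, label_dataset, overlaps,
                       trajectory_level_labels)
from .objectives import (BatchEmbeddings, cosine_sim, motion_loss,
                         physics_loss, total_loss, variance_loss,
                         warmup_weight)
from .pipeline import ablation_matrix, run_arm, run_pipeline
from .relations import (AnchorContext, MemoryBank, RelationGraph,
                        build_relations, contexts_from_labels,
                        stratified_batches)
from .synthetic import FixtureBundle, make_fixture, simulate_dataset
from .training import Encoder, TrainState, embed_dataset, fit

__all__ = [name for name in dir() if not name.startswith("_")]
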