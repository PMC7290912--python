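"""Pipeline configuration: every tunable threshold in one place.

The published characterization was manual (default-parameter BLAST/LALIGN
searches curated by eye), so none of these thresholds are printed values;
they are the package's own operating points, exposed here and in the YAML
config format so users can tighten or relax them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .align import ScoringScheme


@dataclass
class PipelineConfig:
    # Alignment scoring (BLASTN-like defaults).
    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    # Genome-scan thresholds for the ORF models.
    min_score: int = 40
    min_identity: float = 80.0
    # End models are short (23-160 nt); they get a lower score floor.
    min_end_score: int = 30
    # Fragment merging into candidate loci.
    merge_max_gap: int = 3000          # tnpB: bridges the ~2.6 kb nested disruption
    # tnpA carries deletions, never nested insertions, so its fragments
    # are near-adjacent on the genome; a small gap stops chains from
    # reaching the next element's tnpA in densely packed genomes.
    tnpa_merge_gap: int = 200
    # Same rationale as breakpoint_tol: chance-match tails let adjacent
    # fragments claim up to ~12 nt of the same model positions.
    model_overlap_tol: int = 12
    # Boundary extension (element-end delimitation).
    boundary_window: int = 15
    boundary_min_identity: float = 0.6
    # Structural classification.
    # Per-breakpoint tolerance for fingerprint matching.  Local alignment
    # ends wander by up to ~10 nt where flanking sequence happens to
    # continue matching the reference, so this is looser than the
    # sub-5-nt precision of manually curated breakpoints; the nearest
    # fingerprints are >100 nt apart, leaving ample margin.
    breakpoint_tol: int = 12
    event_tol: int = 15                # indel position/length tolerance, nt
    min_insert_len: int = 50           # internal insertions in this range are
    max_insert_len: int = 80           # candidate LI/RI/HI inserts
    disruption_min_len: int = 500      # smallest insertion called a disruption
    disruption_t2bprime_min: int = 1000
    min_tnpa_nt: int = 40              # smallest tnpA coverage worth typing
    # Element assembly and PATE detection.
    pairing_max_gap: int = 500         # max tnpA-tnpB separation within a locus
    region_margin: int = 250           # context extracted around each locus
    pate_max_tnpb_nt: int = 100        # ends-only relics may keep a tnpB tail
    pate_cluster_gap: int = 400
    # A relic call needs at least one solid end match; the shortest
    # genuine component (23-nt RE stub / 28-nt LE hairpin fragment)
    # scores >=46, while chance matches this strong are ~1e-6 per Mb.
    pate_min_best_score: int = 45
    # Replichore / locus numbering.
    origin_position: int = 1
    terminus_position: int | None = None   # default: antipode of the origin
    # Seed for the packaged reference realization.
    reference_seed: int = 605

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
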