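"""Fragment-probe pose clustering and consensus-site ranking.

Three probe types converge on one location (30 poses total) while a single
type docks at a second location (10 poses).  Greedy 3-Å clustering per probe
type, then pooling of cluster representatives, ranks the first location as
consensus site 1 because more probe clusters agree there.
"""

import numpy as np

from ensitemap import build_consensus_sites, cluster_probe_poses, truncate_top_poses
from ensitemap.synthetic import PoseCloudSpec, make_probe_poses

clouds = [
    PoseCloudSpec(center=(0.0, 0.0, 0.0), n_poses=10, sigma=0.5, probe_type="EOH"),
    PoseCloudSpec(center=(0.0, 0.0, 0.0), n_poses=10, sigma=0.5, probe_type="ACN"),
    PoseCloudSpec(center=(0.0, 0.0, 0.0), n_poses=10, sigma=0.5, probe_type="IPA"),
    PoseCloudSpec(center=(15.0, 0.0, 0.0), n_poses=10, sigma=0.5, probe_type="EOH"),
]
poses = make_probe_poses(clouds, seed=1)
print(f"{len(poses)} probe poses of {len({p.probe_type for p in poses})} types")

poses = truncate_top_poses(poses, 2000)   # keep the best-scoring poses per type
clusters = cluster_probe_poses(poses, cutoff=3.0)
print(f"{len(clusters)} probe clusters after greedy 3-Å clustering")

sites = build_consensus_sites(clusters, cs_cutoff=3.0)
for cs in sites:
    print(f"CS rank {cs.rank}: midpoint {np.round(cs.midpoint, 2)}, "
          f"{cs.n_clusters} probe cluster(s) from {cs.n_probe_types} type(s)")
print("\nrank 1 is where independent probe types converge - the hotspot.")
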