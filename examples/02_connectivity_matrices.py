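"""From BOLD time series to a Fisher-z connectivity matrix, with scrubbing.

Shows the outlier-scan step (censor timepoints with framewise displacement
above 0.9 mm or global signal beyond 5 SD) followed by Pearson correlation
and the Fisher transform z = atanh(r).
"""

import numpy as np

from tfconn import default_atlas, default_scenario, generate_cohort, generate_nuisance
from tfconn.connectivity import connectivity_matrix, scrub_with_traces

atlas = default_atlas()
scenario = default_scenario(n_per_group={"HC": 2, "AD": 2}, seed=3)
series, _ = generate_cohort(scenario, atlas)
traces = generate_nuisance(scenario)

ts = series[0]
tr = traces[ts.subject_id]
scrubbed = scrub_with_traces(ts, tr)
print(f"{ts.subject_id}: {ts.n_timepoints} timepoints, "
      f"{ts.n_timepoints - scrubbed.n_timepoints} censored by the outlier scan")

conn = connectivity_matrix(ts, tr)
i, j = atlas.index_of("DefaultMode.MPFC"), atlas.index_of("DefaultMode.PCC")
print(f"within-DMN edge:   r = {conn.r[i, j]:+.3f}, z = {conn.z[i, j]:+.3f}")
k = atlas.index_of("Cerebellar.Anterior")
print(f"cross-network edge: r = {conn.r[i, k]:+.3f}, z = {conn.z[i, k]:+.3f}")
print(f"round trip |tanh(z) - r| max: "
      f"{np.abs(np.tanh(conn.z) - np.where(np.eye(32), 0, conn.r)).max():.2e}")
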