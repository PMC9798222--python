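"""Build the six-shell, 112-encoding acquisition scheme and inspect it.

Directions on each shell are spread by antipodally symmetric electrostatic
repulsion, then the shells are rotated against each other so the whole
scheme samples the sphere jointly.
"""

import itertools

import numpy as np

import cortecs as c

scheme = c.build_protocol(seed=0)
print(f"total encodings: {len(scheme)}")
for b, n in scheme.shell_table:
    dirs = scheme.bvecs[np.isclose(scheme.bvals, b)]
    min_ang = min(
        np.degrees(np.arccos(min(1.0, abs(float(u @ v)))))
        for u, v in itertools.combinations(dirs, 2)
    ) if n > 1 else float("nan")
    print(f"  shell b={b:>6.0f} s/mm^2: {n:>2d} directions, "
          f"min pairwise angle {min_ang:5.1f} deg")

c.acquisition.write_bvals_bvecs(scheme, "protocol.bval", "protocol.bvec")
print("wrote protocol.bval / protocol.bvec (FSL layout)")
print("A larger minimum angle means more uniform angular coverage; the "
      "counts per shell scale with b so high-b shells, which carry the "
      "orientational contrast, are sampled most densely.")
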