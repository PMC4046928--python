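# femtfm — finite-element traction force microscopy for cells and clusters

Adherent cells pull (and sometimes push) on their substrate. Traction force
microscopy (TFM) infers those stresses from the deformation of a soft gel the
cells sit on: fluorescent beads in the gel are imaged with the cells attached
and again after the cells are released, the bead motion gives the surface
displacement field, and an elasticity model turns displacements into traction.

Classical TFM inverts the Boussinesq half-space Green's function, which
assumes the gel is infinitely deep and needs displacement data (and
regularization) everywhere. That breaks down exactly where multi-cellular
mechanics gets interesting: cell clusters can be wider than the gel is thick,
and neighbouring cells' fields overlap. `femtfm` instead solves the inverse
problem as a **mixed boundary value problem of 3D linear elasticity on the
finite gel slab**:

- under the cells (region S_u): the measured displacements u_x, u_y (and u_z
  if available) are prescribed;
- outside the cells (region S_σ): the *exact* traction-free condition
  **t** = 0 is prescribed — no bead data needed there;
- the glass-bonded bottom and the far lateral walls are fixed.

One sparse linear solve then yields the reaction forces at the
displacement-prescribed nodes — the cell tractions. The traction field
obtained this way is unique, needs no regularization, and accounts for the
finite gel thickness. For nearly incompressible gels (polyacrylamide,
ν ≈ 0.47) the in-plane problem decouples from the out-of-plane traction, so
prescribing F_z = 0 lets plain 2D bead imaging recover the in-plane forces
with a small, quantified error.

The package contains:

- `mesh_fem` — structured hexahedral FEM (mean-dilatation trilinear bricks,
  kPa/µm/nN units), mixed-BC solver with reaction extraction, and the
  pedagogical 1D spring-chain analogue;
- `traction_recovery` — the mixed-BC scheme, the iterative whole-field
  alternative (prescribe displacements everywhere, alternately zero the
  spurious extracellular forces and refresh the field until the RMS nodal
  force stabilizes), the self-equilibration error ratio
  ε = ‖Σ**F**‖ / Σ‖**F**‖, and comparison metrics;
- `forward_sim` — synthetic ground truth: self-equilibrated two-cell and
  disk force fields, the forward solver, noise injection, and the Cerruti
  half-space closed form as an analytic oracle;
- `dic` — minimal digital image correlation (normalized cross-correlation,
  sub-pixel quadratic peak) plus a synthetic bead-image generator;
- `studies` — mesh-convergence, Poisson-decoupling, and region-robustness
  analyses as reproducible scripted studies;
- a `tfm` command line (`forward | recover | dic | study | validate`).

## Worked example

Forward-solve a known two-cell force field on a thin gel, then recover it
from the displacements alone:

```python
import numpy as np
from femtfm import (make_two_cell_fixture, forward_surface_displacements,
                    recover_mixed)

fixture = make_two_cell_fixture(thickness=20.0, spacing=4.0, margin=25.0)
disp = forward_surface_displacements(fixture)          # what beads would show
tf, report = recover_mixed(disp.in_plane(), fixture.mask(),
                           fixture.substrate, min_margin=25.0)

peak = np.hypot(fixture.fx, fixture.fy).max()
err = np.hypot(tf.fx - fixture.fx, tf.fy - fixture.fy).max()
print(f"peak nodal force     : {peak:.3f} nN")
print(f"max recovery error   : {err:.2e} nN")
print(f"error ratios eps     : { {c: f'{e:.2e}' for c, e in report.error_ratios.items()} }")
```

prints

```
peak nodal force     : 0.500 nN
max recovery error   : 1.89e-15 nN
error ratios eps     : {1: '1.98e-16', 2: '2.70e-16'}
```

i.e. the prescribed forces come back at solver precision — the computational
face of the uniqueness of the traction solution — and each recovered cell is
self-equilibrated (ε ≈ 0). The same check at full study scale (70 µm gel,
4.84 µm mesh) is `tfm validate`.

The equivalent shell session:

```bash
tfm forward --config cfg.yaml --fixture two_cell --out-disp disp.csv --out-forces truth.csv
tfm recover --disp disp.csv --mask mask.tif --config cfg.yaml --method mixed --out traction.csv
```

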