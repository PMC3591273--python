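# pocketeer

Target-restricted detection of "deep" surface pockets on proteins, a
pocket-volume biasing energy term, and a seeded Metropolis Monte Carlo
torsion sampler that uses the bias to enrich pocket-containing
conformations — plus the ensemble analytics (minimum interface RMSD to
bound references, pocket hydrophobic surface fraction, cumulative volume
curves, matched random-site selection) needed to compare biased and
unbiased ensembles.

## How it works

1. **Detection** (`pocketeer.pocketgrid`): a cubic 1 Å grid is centered
   on a chosen target residue; points are labeled protein / surface /
   solvent; linear scans along 7 (or 13) directions count
   surface–solvent–surface events with a 12 Å span cap; event-rich
   solvent points become pocket candidates; candidates within 2.5 Å of
   bulk solvent are *surface pocket*, the rest *deep pocket*; connected
   components are clustered and the deep volume of the largest pocket in
   contact with the target is reported. A naive brute-force oracle
   (`pocketeer.oracle`) reproduces the labeling bit-for-bit on small
   grids and anchors the test suite.
2. **Bias** (`pocketeer.biasenergy`): an energy term linear in the deep
   pocket volume (−0.25 units/Å³ moderate, −2.5 strong) added to a
   documented simplified base energy (soft-sphere clash + contact reward
   + torsion restraint).
3. **Sampling** (`pocketeer.sampler`): seeded Metropolis MC over
   sidechain/backbone torsions, one independent RNG substream per run,
   final conformation of each run collected into an ensemble.
4. **Analytics** (`pocketeer.ensana`): Kabsch-superposed interface RMSD
   (minimum over a reference set), Shrake–Rupley SASA and %hSASA of
   pocket linings, cumulative volume curves, and secondary-structure- and
   exposure-matched random surface sites.
5. **Fixtures** (`pocketeer.fixtures`): synthetic PDB structures with
   analytically known geometry (flask with a 125 Å³ cavity, slabs,
   channels, hollow shells, a two-state hinge with exactly two clash-free
   rotamers, and a 20-residue polyalanine fold), so everything is
   testable offline. `pocketeer.benchmark` defines the reference
   two-state protocol, including an exact 1° Boltzmann quadrature that
   the sampler is validated against.

## CLI

```bash
pocketeer fixtures --out fixtures/                 # write the toy suite
pocketeer detect  --pdb fixtures/flask.pdb --target A:2
pocketeer sample  --pdb protein.pdb --target A:52 --bias moderate \
                  --runs 200 --steps 500 --seed 1 --out run1
pocketeer analyze --ensemble run1.pdb --target A:52 \
                  --refs bound1.pdb,bound2.pdb --out report.json
```

`detect` prints a JSON report (per-pocket deep/total volumes, target
contact flags, full config with provenance); `sample` writes a
multi-model PDB plus a JSON sidecar with per-run energy breakdowns, deep
volumes and acceptance ratios; `analyze` computes per-conformation deep
volumes, cumulative volume curves and (given inhibitor-bound references)
minimum interface RMSDs. Detector parameters can be overridden with
`--params params.yaml` (`pocket:` block).

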