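# knapkin

Upper-limb kinematics of percussive tool use (Oldowan-style stone
knapping): a tested pipeline from 6-DOF electromagnetic motion-capture
streams to joint angles, strike energetics, flake-mass task performance,
and movement-synergy PCA — together with a synthetic forward-kinematics
rig that generates every input with known ground truth.

## The problem

Removing a stone flake from a flint core by hardhammer percussion is a
goal-directed action whose success is governed by *functional parameters*
— above all the kinetic energy delivered at the hammer's working point —
rather than by any particular arm movement. Studying this requires:

1. reconstructing a 9-DOF model of the striking arm (3 rotational degrees
   of freedom at shoulder, elbow and wrist) from four segment-mounted
   6-DOF sensors, stylus-calibrated anatomical landmarks (CAST), a
   sphere-fit glenohumeral joint center, epicondyle/styloid midpoints, and
   segment-length optimization against soft-tissue artifact;
2. segmenting striking movements: a strike starts at the hand sensor's
   highest vertical point prior to the blow and ends at its lowest point
   or when it slows below 4.17 × 10⁻³ m/s (the 240 Hz frame interval read
   as a speed);
3. computing, per strike, the maximal kinetic energy `Ek = ½ m v²` at the
   hammer working point, the potential energy at movement start
   `Ep = m g h` above the striking surface, and the ratio `Ek/Ep`
   (values above 1 imply muscular work beyond gravity);
4. quantifying task performance from flake masses (mean, median, SD,
   range, `CV = SD/mean × 100`) with Welch t-tests over the six group
   pairs at a Bonferroni-adjusted `α = 0.05/6`;
5. characterizing coordinative structure per strike by PCA of the 9 × 9
   joint-angle covariance matrix, `φᵢ(t) − φ_Mi = Σₖ w_kᵢ ξₖ(t)`, and
   comparing PC1 loadings between a subject's successful strikes by
   |Pearson r| with a 0.7 significance cutoff.

No raw data of this kind is publicly deposited, so the package ships a
forward-kinematics rig (`knapkin.rig`) that simulates cohorts of four
skill groups — uninitiated, novice, intermediate, expert — whose energy
profiles, strike economy and flake-mass dispersion mirror the published
group summaries. Every generated quantity is retained as ground truth, so
each analysis stage has an exact recovery oracle.

## Worked example

```python
from knapkin.pipeline import simulate_and_analyze

study, results, diagnostics = simulate_and_analyze(seed=1)
print(diagnostics[["group", "ek_true_mean", "ek_est_mean"]])
```

The default cohort (19 subjects in groups of 6/6/3/4, three flake attempts
each, up to three strikes per attempt) yields 78 strikes of which 54
produced a flake. The pipeline's group means of maximal kinetic energy
against the generator's ground truth:

```
       group  ek_true_mean  ek_est_mean
 uninitiated         13.06        12.98
      novice          4.20         4.23
intermediate          5.75         5.76
      expert          3.91         3.92
```

Uninitiated strikers deliver about three times the kinetic energy of every
practiced group (all three pairwise Welch tests significant at α = 0.05/6
— p ≤ 2 × 10⁻⁸ here), the classic signature of not understanding the
fracture mechanics; potential energy falls with expertise (novice vs
expert significant). PC1 of the per-strike joint-angle PCA carries 78% of
joint-angle variance on average (PC2 18%), lowest in the uninitiated group
(74%), and no subject shows |r| > 0.7 between PC1 loadings in *all*
pairwise comparisons of their successful strikes — flake production does
not require a repeatable joint coordination pattern.

The same run as a sequence of narrative steps:

```bash
python analysis/01_simulate_cohort.py --seed 1   # sensor streams -> scratch/study
python analysis/02_reconstruct_and_segment.py    # full pipeline -> results/pipeline
python analysis/03_functional_parameters.py      # Ek, Ep, Ek/Ep by group + tests
python analysis/04_task_performance.py           # flake-mass table + allocation
python analysis/05_coordination_synergy.py       # PC summaries + loading |r|
```

A `knapkin` console script exposes the same stages
(`simulate`, `calibrate`, `analyze`, `report`, `demo`).

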