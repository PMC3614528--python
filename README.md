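# cuffsearch

Automated determination of peripheral-nerve stimulation parameters for
multi-contact cuff electrodes.

Selective stimulation of a peripheral nerve through a multi-contact cuff can
activate individual fascicles and so drive individual muscles — but only if
one knows **which combination of electrode contacts (CEC)** and **which set
of stimulus parameter values (SPV)** produces the desired effector response.
With a 12-contact cuff, three pulse durations, four amplitudes and optional
steering pulses, the admissible space already contains hundreds of stimuli,
and mapping it by hand takes hours of experiment time that an acute
preparation does not have.

`cuffsearch` implements two routines for this problem, plus everything
needed to run them without hardware:

- **Mapping routine** — systematic stimulus–response mapping: every
  admissible (SPV, CEC) combination is delivered *n* times; the mean
  displacement and its variability are recorded, and the combination whose
  response lies closest to a desired displacement can be selected afterwards.
- **Automated search routine** — an adaptive, charge-ordered search: stimuli
  are delivered in ascending total charge across all still-active CECs, each
  mean response is compared with the desired displacement, and CECs whose
  responses are significantly off-direction or stronger than desired are
  *excluded* from all higher charges. The first stable in-tolerance response
  terminates the search, so a successful search returns the lowest-charge
  admissible solution. Optional strategies: a response cache shared between
  searches, a dual-rate charge ladder, and overshoot bisection.
- **Synthetic plant** — a seeded simulator of the stimulated nerve–muscle–paw
  chain (sigmoidal recruitment of directional muscle groups, per-contact
  selectivity, repetition noise, slow gain drift) that closes the loop for
  testing and benchmarking.
- **Response metrics** — displacement estimation by double integration of
  frontal-plane acceleration over the first 80 ms after stimulation, and the
  variability statistic used to gate unstable responses.

## The quantities at the core

The effector response to one stimulus is the maximal 2-D paw displacement
(x = add-/abduction, y = plantar-/dorsiflexion). Repeating a stimulus *n*
times yields displacements (xᵢ, yᵢ) with mean (x̄, ȳ) and **variability**

    F = (1/n) Σᵢ √((x̄ − xᵢ)² + (ȳ − yᵢ)²) · 100 / √(x̄² + ȳ²)   [%]

i.e. the mean distance of the repetitions from their mean, as a percentage
of the mean magnitude. Responses with F above an operator limit (default
10 %) are skipped. A search succeeds when a stable mean response lies inside
the **tolerance circle** — within 15 % (default) of the desired
displacement's magnitude around the desired displacement. A significant
response (≥ 0.5 mm) deviating more than 60° in direction, or exceeding the
desired magnitude, excludes its CEC from all higher charges. The **total
charge** of a stimulus is `duration × (main amplitude + steering amplitude)`
(μs·μA → reported in nC) and defines the search order.

## Worked example

The shipped configuration describes the reference protocol on a 12-contact
cuff (rows A–C × contacts I–IV): row-B main cathodes with same-index
flanking grounds, one optional auxiliary row-B contact, durations 10/20/40 μs,
amplitudes 50–400 μA, steering fractions 50/100 %:

```
$ cuffsearch enumerate
contact configurations: 40
stimuli (SPV x CEC):    768
```

Searching the simulated plant for a 7.77 mm displacement at 25.4°:

```
$ cuffsearch search --plant paperlike --seed 7 --target "7.77,25.4" --out demo
status: found
found:  BII|steer+:BIII|gnd:AII+CII/10us/400uA@1 (8 nC)
stimuli tested: 477
```

The search found a stable in-tolerance stimulus — main cathode BII with an
anodic steering pulse on BIII at 100 % of the 400 μA main amplitude, 10 μs
pulses, 8 nC total — after testing 477 of the 768 combinations (the
exhaustive mapping would have tested all 768). `demo/` contains the trial
log (`trials.csv`, one row per repetition), the decision log
(`decisions.jsonl`: accept/exclude/skip/continue with reasons), a summary
and a manifest snapshotting the run inputs.

The same machinery is available as a library:

```python
import cuffsearch as cs

bundle = cs.load_config(cs.default_config_path()).with_target(7.77, 25.4)
plant = cs.load_plant("paperlike", seed=7)
result = cs.run_search(plant, bundle.layout, bundle.constraints,
                       bundle.grid, bundle.routine)
print(result.status, result.found_stimulus.charge_nc)   # found 8.0
```

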