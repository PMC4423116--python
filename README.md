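# paddleclamp

Quantitative analysis of how inhibitor-cystine-knot (ICK) peptide toxins
from tarantula venom engage ion channels: how strongly they partition
into lipid membranes, how tightly they occupy their channel binding
sites, and which surfaces mediate the interaction. The package targets
the kind of study in which a voltage-sensor toxin (e.g. GxTx-1E, which
inhibits the Kv2.1 potassium channel) is compared with an
acid-sensing-channel toxin (e.g. PcTx1, which binds the ASIC1a thumb
helix), combining fluorescence spectroscopy, two-electrode voltage-clamp
electrophysiology and structural surface mapping.

## What it computes

**Membrane partitioning** (`paddleclamp.spectro`). Tryptophan emission
spectra blue-shift and brighten when a toxin moves from water into a
bilayer. The mole-fraction partition coefficient is fit from a lipid
titration of normalised fluorescence:

    F/F0(L) = 1 + (F/F0_max − 1) · K_x[L] / ([W] + K_x[L])

with [L] the available lipid molarity (60 % of total by default) and
[W] = 55.3 M water. The same functional form fit to acrylamide
*dequenching* titrations gives K_dx, and linear Stern–Volmer fits
F0/F = 1 + K_sv[Q] quantify quencher accessibility. Blue-shift and
brominated-lipid quench-profile metrics complete the membrane picture.

**Occupancy energetics** (`paddleclamp.occupancy`). With four
independent toxin sites per channel and single occupancy sufficient to
hold the channel shut at weak depolarisations, the fraction of unbound
channels is F_u = I/I0 = (K_d/(K_d+[T]))⁴, inverted exactly as
K_d = (1/(1 − F_u^¼) − 1)[T]. Alanine-scan tables are converted to
binding perturbation energies ΔΔG = RT·ln(K_d^mut/K_d^wt) at 298.15 K.
G–V relations from tail currents (with optional Boltzmann summaries)
round out the electrophysiology.

**Binding surfaces** (`paddleclamp.structmap`). Kabsch superposition of
matched atom sets (e.g. cystine Cα of two ICK toxins), Shrake–Rupley
solvent-accessible surface area with a 1.4 Å probe on a deterministic
960-point quadrature, per-residue ΔSASA interface footprints, connected
hydrophobic-patch areas, register-shifted grafting of a toxin against a
target helix (100° twist / 1.5 Å rise per one-residue frame) and
steric-clash / interface-residue screens.

**Synthetic data** (`paddleclamp.synthdata`) generates spectra,
titrations, occupancy experiments and toy helix–toxin complexes with
known ground truth, so the entire pipeline is testable end to end
without any external data.

## Worked example

Generate a noisy synthetic lipid titration at the conditions of a
strong membrane partitioner and refit it:

```sh
$ paddleclamp synth partition --k 4.6e6 --f-max 2.3 --noise-sd 0.02 \
      --seed 1 --out titration.csv
$ paddleclamp spectro fit-kx titration.csv
{
  "K": 4513641.819429385,
  "f_max": 2.3142453361182223,
  "K_stderr": 233534.71944345144,
  "f_max_stderr": 0.013485068397070471,
  ...
}
```

The fitted K_x of 4.51 × 10⁶ recovers the generating coefficient
4.6 × 10⁶ within its standard error — a mole-fraction coefficient of
this size means the toxin is several-million-fold enriched in the
membrane phase relative to water, and f_max ≈ 2.3 is the fluorescence
gain at full partitioning.

Recompute the alanine-scan energetics from the packaged affinity table:

```sh
$ paddleclamp occupancy ddg
       toxin  kd_nM  kd_sem_nM  ratio  ddg_kcal_mol  ratio_calc  ddg_calc
GxTx-1E(Nle)    224       25.0    1.0           NaN    1.000000  0.000000
         E1A    414       38.0    1.8          0.36    1.848214  0.363915
         ...
```

`ddg_calc` is RT·ln of the K_d fold-change: mutants with ΔΔG above
~2 kcal mol⁻¹ (F7A, W8A, Y22A, W28A, ...) mark the aromatic-rich active
surface of the toxin.

The same operations are available as library calls
(`spectro.fit_mole_fraction_partition`, `occupancy.kd_four_site`,
`structmap.delta_sasa`, ...) and through a JSON-configured pipeline
driver (`paddleclamp run config.json`).

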