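# Example end-to-end synthetic study (moderate scale, runs in ~1 min).
# Run:  excispec all -c examples/config.yaml -o out
channels: 2048
window_ns: 50.0
irf_fwhm_ps: 80.0
irf_t0_ns: 2.0
wavelengths: [370.0, 380.0, 390.0]
peak_counts: 10000
sample_preset: y40a_substrate
ds_reference_preset: double_flap
ss_reference_preset: single_strand
n_components: 4
n_boot: 10
dna_concentration_m: 1.0e-5        # 10 uM construct
residues_2ap_per_strand: 2
pathlength_cm: 1.0
smoothing_width: 5
cd_n_scans: 5
cd_unpaired_fractions: [0.0, 0.25, 0.51, 0.83, 0.98]
cd_noise_sd: 0.02
seed: 1
outdir: out
make_plots: false
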