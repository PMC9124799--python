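task: patterns
seed: 0
out_dir: runs
tau_m: 15.0
tau_out: 10.0
tau_a: 200.0
v_th: 1.0
beta_adapt: 0.4902
t_refrac: 5.0
delay_ms: 1.0
dt: 1.0
g_l: 0.1
g_b: 0.2
c_m: 2.0
tau_l: 10.0
tau_s: 2.5
f_target: 20.0
lam_f: 1.0
lam_v: 0.01
sigma1: 1.0
sigma2: 4.0
lam_mix: 0.5
eta1: 0.1
eta2: 10.0
n_hsnn: 440
n_tlif: 180
n_psnn: 239
q_ada: 0.405
t_img: 20.0
n_way: 5
k_shot: 1
n_classes: 1000
n_per_class: 25
n_neurons: 100
duration_ms: 200.0
rate_low: 2.0
rate_high: 50.0
sigma_noise: 0.0
p_del: 0.0
flip_frac: 0.15
motor_duration_ms: 500.0
n_clock: 20
link1: 0.5
link2: 0.5
n_batch: 285
n_iters: 1000
lr: 0.001915
lr_out: 0.002
eta_inner: 0.05
tau_ls: 10.0
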