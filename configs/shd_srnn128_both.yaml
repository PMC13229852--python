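# FC-128 SRNN on SHD: learnable synaptic delays at input and recurrent synapses.
shd_train: data/shd_train.h5
shd_test: data/shd_test.h5
n_hidden: 128
recurrent: true
flavor_in: synaptic
flavor_rec: synaptic
learn_w: true
learn_d: true
density: 1.0
delay_init: uniform
epochs: 60
seeds: [0, 1, 2, 3, 4]
eval_every: 1
sim: {alpha: 0.6, v_th: 1.0, dt: 10.0, T: 100, D_max: 25}
rates: {lr_w: 1.0e-4, lr_d: 1.0e-2, batch_size: 16}
kernel: {sigma: 2.0, k: 12}
out_dir: results/shd_srnn128_both
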