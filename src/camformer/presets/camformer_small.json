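{
 "conv_channels": [
  256,
  256,
  256,
  256,
  256,
  256
 ],
 "kernel_sizes": [
  9,
  9,
  9,
  9,
  7,
  7
 ],
 "residual_after": [
  2,
  4,
  6
 ],
 "penultimate_maxpool": true,
 "pool_width": 11,
 "fc_dims": [
  256,
  64
 ],
 "dropout": [
  0.1,
  0.1
 ],
 "activation": "relu",
 "batchnorm": true,
 "input_channels": 4,
 "seq_len": 110
}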