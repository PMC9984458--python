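# cmsflnet

A compact convolutional image classifier built on **consecutive multiscale
feature learning**, for small labeled image sets — few samples per class,
small image sides, possibly imbalanced classes (the regime of many medical
imaging datasets: CT slices, histopathology patches, MRI sections).

## The idea

Ordinary multiscale CNNs extract features at several receptive fields (RFs)
in parallel, paying for each scale independently. The CMSFL block grows its
RF *consecutively*: a main branch of four Conv(3×3)–BN–ReLU units deepens
stage by stage (RF 3 → 5 → 7 → 9), and at each stage after the first a
secondary branch applies one fresh 3×3 convolution to the unpooled block
input and concatenates it channel-wise:

```
u1 = CBA(mb1, x)                      u_k, k = 2..4:
u_k = [ CBA(mb_k, u_{k-1}) | CBA(sb_{k-1}, x) ]
```

After stage 4 the block's channel groups span the RF set (9, 7, 5, 3) at a
cost of 2k−1 = 7 convolutions, where a traditional stack that rebuilds each
RF independently needs k(k+1)/2 = 10. The concatenated low-RF channels keep
original-input information alive across the 2×2 max-poolings between
blocks. The network is N blocks (default 6) + pooling each, then a
bias-free head — by default a cosine-normalized classifier,
score_c = α·cos(f, w_c) — trained with class-weighted categorical
cross-entropy

```
L = −(1/M) Σ_j Σ_i ω_j · y_i^j · log p_i^j
```

with inverse-frequency ω_j by default. Everything, including
backpropagation and Adam, is implemented in NumPy; see `docs/methods.md`
for the model account and numerical choices.

## Worked example

```python
import cmsfl

spec = cmsfl.SyntheticSpec(n_classes=3, counts_per_class=(50, 50, 50),
                           image_side=64, noise_sd=0.05, difficulty=0.0,
                           seed=11)
ds = cmsfl.generate_dataset(spec)
train_set, val_set, _ = cmsfl.split_dataset(ds, (0.8, 0.2, 0.0), seed=11)

cfg = cmsfl.NetworkConfig(num_modules=6, filters=32, num_classes=3,
                          input_side=64)
tc = cmsfl.TrainConfig(epochs=20, seed=11, augmentation=None,
                       target_train_as=0.97)
params, history = cmsfl.train(train_set, val_set, cfg, tc)
for r in history.records[-2:]:
    print({k: round(v, 4) for k, v in r.items()})

labels, probs = cmsfl.predict(params, params._train_stats, train_set.images)
print("train AS:", cmsfl.evaluate(labels, train_set.labels, 3).as_score)
```

prints (one line per epoch; training stopped at epoch 5, when eval-mode
training accuracy crossed the 0.97 target):

```
{'epoch': 4, 'train_loss': 0.1413, 'val_loss': 0.5636, 'val_as': 0.9333, 'val_f1': 0.9327, 'train_as': 0.8167}
{'epoch': 5, 'train_loss': 0.1384, 'val_loss': 0.408, 'val_as': 1.0, 'val_f1': 1.0, 'train_as': 0.975}
train AS: 0.975
```

`train_loss` is the weighted cross-entropy averaged over mini-batches;
`val_as`/`val_f1` are accuracy and macro-F1 on the held-out split,
standardized with the *training* statistics — `predict` enforces that
contract by digest and refuses foreign statistics.

The cost ledger is exact and cross-checked against the parameter archive:

```python
report = cmsfl.network_cost(cfg)
print(report.total_params)        # 651457 — equals the built network's count
print(cmsfl.consecutive_conv_count(4), cmsfl.traditional_conv_count(4))  # 7 10
```

## Command line

```
cmsfl synth --classes 3 --counts 50,50,50 --side 64 --seed 0 --out data/
cmsfl train --data data/ --modules 6 --img-size 64 --epochs 50 --out run/
cmsfl predict --run run/ --data data/ --out preds.json
cmsfl cost --modules 6 --filters 32 --img-size 64 --classes 3
cmsfl ablate --data data/ --sizes 4,6 --img-size 64
```

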