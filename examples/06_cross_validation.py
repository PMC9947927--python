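"""Stringent cross-validation of the full image pipeline.

Generates a small synthetic corpus, separates stains, extracts all five
descriptor sets, and runs stratified k-fold CV in which feature
selection, scaling and all SAE training are redone inside every fold.
"""

from subloc2l.evaluation import stratified_kfold_cv
from subloc2l.features.api import extract_dataset
from subloc2l.fixtures import SyntheticSpec, generate_dataset
from subloc2l.imaging import separate_stains
from subloc2l.sae import SAEConfig
from subloc2l.two_level import TwoLevelConfig

spec = SyntheticSpec(n_classes=4, images_per_class=9, image_size=(64, 64), seed=0)
images, labels, _ = generate_dataset(spec)
pairs = [separate_stains(img.astype(float), spec.stain_basis) for img in images]
sets = extract_dataset(pairs, labels)

cfg = TwoLevelConfig(
    first_level=SAEConfig(hidden1=6, hidden2=4, pretrain_epochs=30, finetune_epochs=120),
    second_level=SAEConfig(hidden1=4, hidden2=4, pretrain_epochs=30, finetune_epochs=120),
    stacking_folds=2, max_features=6, seed=0,
)
folds, pooled = stratified_kfold_cv(list(sets.values()), k=3, cfg=cfg, seed=0)

for k, rep in enumerate(folds):
    print(f"fold {k}: OA={rep.oa:.3f} F1={rep.f1_macro:.3f}")
print(f"pooled: OA={pooled.oa:.3f} F1={pooled.f1_macro:.3f} "
      f"MCC={pooled.mcc:.3f} meanAUC={pooled.mean_auc:.3f}")
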