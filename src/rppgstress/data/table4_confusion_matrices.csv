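# Published pooled 10-fold confusion matrices, one per (classifier, dataset
# variant). Cell order note: cells are stored as tp,fn,fp,tn where fn is the
# SECOND and fp the THIRD value as printed. The published off-diagonal
# captions label these (FP) and (FN) respectively, but that labelling is
# inconsistent with the published sensitivity/specificity values (e.g. SVM
# variant 1 sensitivity 0.86 = 283/(283+45), not 283/(283+68)); accuracy and
# kappa are invariant to the swap. The J48 variant-3 row sums to 606 instead
# of the common total 706 (apparent misprint) and is flagged inconsistent.
classifier,dataset,tp,fn,fp,tn,sum_consistent
svm_puk,1,283,45,68,310,True
svm_puk,2,91,64,260,291,True
svm_puk,3,289,3,62,352,True
svm_puk,4,234,191,117,164,True
svm_puk,5,312,0,39,355,True
knn,1,302,66,49,289,True
knn,2,186,164,165,191,True
knn,3,322,51,29,304,True
knn,4,207,138,144,217,True
knn,5,338,15,13,340,True
c45,1,283,44,68,311,True
c45,2,0,0,351,355,True
c45,3,295,12,56,243,False
c45,4,73,44,278,311,True
c45,5,328,5,23,350,True
random_forest,1,298,44,53,311,True
random_forest,2,186,164,165,191,True
random_forest,3,318,37,33,318,True
random_forest,4,203,138,148,217,True
random_forest,5,338,12,13,343,True
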