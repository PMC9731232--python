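category,condition,trial,count
Hypopigmentation,Thioridazine,1,7
Hypopigmentation,Thioridazine,2,1
Hypopigmentation,Thioridazine,3,1
Hypopigmentation,Thioridazine,4,22
Hypopigmentation,Thioridazine,5,1
Hypopigmentation,Thioridazine,6,11
Hypopigmentation,Control,1,0
Hypopigmentation,Control,2,0
Hypopigmentation,Control,3,0
Hypopigmentation,Control,4,0
Hypopigmentation,Control,5,0
Hypopigmentation,Control,6,0
Kinked body,Thioridazine,1,4
Kinked body,Thioridazine,2,4
Kinked body,Thioridazine,3,4
Kinked body,Thioridazine,4,1
Kinked body,Thioridazine,5,2
Kinked body,Thioridazine,6,14
Kinked body,Control,1,0
Kinked body,Control,2,0
Kinked body,Control,3,6
Kinked body,Control,4,5
Kinked body,Control,5,3
Kinked body,Control,6,0
Edema,Thioridazine,1,4
Edema,Thioridazine,2,1
Edema,Thioridazine,3,1
Edema,Thioridazine,4,46
Edema,Thioridazine,5,18
Edema,Thioridazine,6,6
Edema,Control,1,0
Edema,Control,2,0
Edema,Control,3,6
Edema,Control,4,2
Edema,Control,5,1
Edema,Control,6,0
Abnormal face shape,Thioridazine,1,12
Abnormal face shape,Thioridazine,2,2
Abnormal face shape,Thioridazine,3,2
Abnormal face shape,Thioridazine,4,55
Abnormal face shape,Thioridazine,5,0
Abnormal face shape,Thioridazine,6,10
Abnormal face shape,Control,1,0
Abnormal face shape,Control,2,0
Abnormal face shape,Control,3,0
Abnormal face shape,Control,4,0
Abnormal face shape,Control,5,0
Abnormal face shape,Control,6,0
Gut,Thioridazine,1,9
Gut,Thioridazine,2,0
Gut,Thioridazine,3,0
Gut,Thioridazine,4,0
Gut,Thioridazine,5,0
Gut,Thioridazine,6,3
Gut,Control,1,2
Gut,Control,2,0
Gut,Control,3,3
Gut,Control,4,0
Gut,Control,5,2
Gut,Control,6,0
Cleft cement gland,Thioridazine,1,0
Cleft cement gland,Thioridazine,2,4
Cleft cement gland,Thioridazine,3,4
Cleft cement gland,Thioridazine,4,0
Cleft cement gland,Thioridazine,5,0
Cleft cement gland,Thioridazine,6,19
Cleft cement gland,Control,1,0
Cleft cement gland,Control,2,0
Cleft cement gland,Control,3,0
Cleft cement gland,Control,4,0
Cleft cement gland,Control,5,0
Cleft cement gland,Control,6,0
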