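wt,mut,effect
A,C,0.888269
A,D,0.774811
A,E,1.542555
A,F,0.141874
A,G,1.632651
A,H,0.384741
A,I,0.150437
A,K,1.242711
A,L,-0.779178
A,M,1.090473
A,N,1.071686
A,P,0.844850
A,Q,-0.377751
A,R,1.057023
A,S,1.187106
A,T,0.122359
A,V,0.554522
A,W,1.422395
A,Y,0.375165
C,A,-1.212030
C,D,-0.573753
C,E,0.324466
C,F,-0.380806
C,G,0.298293
C,H,-0.756416
C,I,-1.015895
C,K,0.174031
C,L,-1.754760
C,M,-0.009583
C,N,0.252394
C,P,-0.245164
C,Q,-1.719986
C,R,0.247456
C,S,0.719742
C,T,-0.477609
C,V,0.052882
C,W,0.337006
C,Y,-0.597601
D,A,-0.881000
D,C,0.038820
D,E,0.811534
D,F,0.018844
D,G,0.705424
D,H,-0.501396
D,I,-0.462062
D,K,0.691534
D,L,-1.460889
D,M,0.577338
D,N,0.357279
D,P,-0.232646
D,Q,-1.446572
D,R,0.622574
D,S,0.898853
D,T,-0.571575
D,V,0.038127
D,W,0.584081
D,Y,0.153640
E,A,-1.309318
E,C,-0.311354
E,D,-0.563040
E,F,-1.186796
E,G,-0.053602
E,H,-0.692396
E,I,-1.506087
E,K,-0.111861
E,L,-2.000000
E,M,-0.163800
E,N,-0.006882
E,P,-0.927948
E,Q,-1.666938
E,R,-0.250463
E,S,-0.188474
E,T,-1.048341
E,V,-0.441641
E,W,0.067070
E,Y,-0.965919
F,A,-0.671555
F,C,0.343129
F,D,0.384390
F,E,1.185918
F,G,1.121952
F,H,0.093012
F,I,-0.319927
F,K,0.529532
F,L,-0.947410
F,M,0.760594
F,N,0.618176
F,P,0.002445
F,Q,-0.657732
F,R,0.933151
F,S,0.965650
F,T,-0.253973
F,V,0.170102
F,W,0.722514
F,Y,0.429008
G,A,-1.464180
G,C,-0.548688
G,D,-0.407673
G,E,-0.250746
G,F,-0.830266
G,H,-0.715325
G,I,-1.044865
G,K,-0.216814
G,L,-2.000000
G,M,-0.184099
G,N,-0.265894
G,P,-0.569600
G,Q,-2.000000
G,R,0.108910
G,S,0.062319
G,T,-1.008200
G,V,-0.473210
G,W,0.106370
G,Y,-0.828611
H,A,-0.122992
H,C,0.759948
H,D,0.154007
H,E,1.251060
H,F,0.069618
H,G,1.122417
H,I,-0.604606
H,K,0.594702
H,L,-1.013588
H,M,0.653352
H,N,0.858436
H,P,0.162400
H,Q,-1.101264
H,R,0.837812
H,S,1.169503
H,T,0.225757
H,V,0.320492
H,W,0.774198
H,Y,0.100237
I,A,0.088934
I,C,0.860567
I,D,0.621908
I,E,1.308523
I,F,0.257983
I,G,1.442537
I,H,0.443252
I,K,1.402523
I,L,-0.543112
I,M,1.333679
I,N,1.137854
I,P,0.448146
I,Q,-0.374856
I,R,1.174469
I,S,1.442978
I,T,0.527854
I,V,0.766495
I,W,1.379379
I,Y,0.578993
K,A,-0.962289
K,C,0.057475
K,D,-0.566867
K,E,0.175952
K,F,-0.540951
K,G,0.116586
K,H,-0.702184
K,I,-0.890997
K,L,-1.901184
K,M,-0.228629
K,N,-0.181646
K,P,-0.675488
K,Q,-1.823137
K,R,0.336147
K,S,0.244094
K,T,-1.039746
K,V,-0.206768
K,W,0.293102
K,Y,-0.832961
L,A,0.604413
L,C,1.229682
L,D,1.107663
L,E,1.739133
L,F,1.106802
L,G,1.764453
L,H,0.787603
L,I,0.870170
L,K,1.983127
L,M,1.954952
L,N,1.785627
L,P,1.074838
L,Q,0.063879
L,R,1.557316
L,S,1.743563
L,T,0.621560
L,V,1.216618
L,W,1.561140
L,Y,1.027995
M,A,-1.207068
M,C,-0.256698
M,D,-0.632979
M,E,0.450629
M,F,-0.821099
M,G,0.104699
M,H,-0.615304
M,I,-1.340821
M,K,0.017651
M,L,-1.985450
M,N,0.042597
M,P,-0.668339
M,Q,-1.402613
M,R,0.028914
M,S,0.243382
M,T,-0.841694
M,V,-0.440551
M,W,0.012006
M,Y,-0.816525
N,A,-1.251717
N,C,-0.503240
N,D,-0.498790
N,E,0.279530
N,F,-0.742596
N,G,-0.017671
N,H,-0.880256
N,I,-1.026907
N,K,0.181489
N,L,-1.961346
N,M,-0.137222
N,P,-0.882745
N,Q,-1.998315
N,R,-0.119990
N,S,0.083494
N,T,-1.173012
N,V,-0.462120
N,W,0.209820
N,Y,-0.724634
P,A,-0.606874
P,C,0.268174
P,D,0.213884
P,E,0.839948
P,F,0.010805
P,G,1.044936
P,H,-0.323938
P,I,-0.500003
P,K,0.612775
P,L,-1.202496
P,M,0.303436
P,N,0.728935
P,Q,-1.175329
P,R,0.830258
P,S,0.969565
P,T,-0.014861
P,V,0.401896
P,W,0.700486
P,Y,-0.202290
Q,A,0.609091
Q,C,1.289236
Q,D,1.135319
Q,E,2.000000
Q,F,1.000667
Q,G,2.000000
Q,H,1.017207
Q,I,0.709935
Q,K,1.753498
Q,L,-0.284535
Q,M,1.673810
Q,N,1.520462
Q,P,1.168580
Q,R,1.710229
Q,S,1.948211
Q,T,0.659516
Q,V,1.104499
Q,W,1.686214
Q,Y,1.161761
R,A,-1.402970
R,C,-0.594360
R,D,-0.878881
R,E,-0.135890
R,F,-0.627138
R,G,-0.133493
R,H,-0.974337
R,I,-1.387523
R,K,-0.224865
R,L,-2.000000
R,M,-0.029146
R,N,-0.212890
R,P,-1.006698
R,Q,-1.659261
R,S,0.225122
R,T,-0.881548
R,V,-0.614116
R,W,0.201198
R,Y,-0.618924
S,A,-1.624281
S,C,-0.658618
S,D,-0.719652
S,E,-0.269653
S,F,-0.866371
S,G,0.222280
S,H,-0.804746
S,I,-1.395510
S,K,-0.281513
S,L,-2.000000
S,M,-0.299308
S,N,-0.408894
S,P,-0.677318
S,Q,-1.692966
S,R,-0.103118
S,T,-1.359117
S,V,-0.954076
S,W,-0.432596
S,Y,-0.878495
T,A,-0.278355
T,C,0.508771
T,D,0.470168
T,E,0.894799
T,F,0.203810
T,G,1.290678
T,H,0.024416
T,I,-0.563554
T,K,0.781956
T,L,-1.163749
T,M,0.526970
T,N,0.855815
T,P,0.288926
T,Q,-0.911141
T,R,0.815562
T,S,1.109832
T,V,0.383961
T,W,1.123366
T,Y,0.236147
V,A,-0.458209
V,C,0.295432
V,D,-0.145215
V,E,0.632930
V,F,-0.405933
V,G,0.380797
V,H,-0.389642
V,I,-0.829491
V,K,0.300044
V,L,-1.352810
V,M,0.220324
V,N,0.321855
V,P,-0.042044
V,Q,-1.094479
V,R,0.401062
V,S,0.465595
V,T,-0.411606
V,W,0.658650
V,Y,-0.005523
W,A,-1.290300
W,C,-0.326182
W,D,-0.840706
W,E,-0.087889
W,F,-0.780355
W,G,-0.071687
W,H,-0.642233
W,I,-1.201596
W,K,-0.156927
W,L,-1.851509
W,M,-0.268436
W,N,0.265954
W,P,-0.438837
W,Q,-1.505083
W,R,0.209487
W,S,0.450299
W,T,-0.937302
W,V,-0.632414
W,Y,-0.726554
Y,A,-0.622794
Y,C,0.321173
Y,D,-0.232636
Y,E,0.503810
Y,F,-0.358499
Y,G,0.659668
Y,H,-0.325833
Y,I,-0.757431
Y,K,0.298580
Y,L,-1.374976
Y,M,0.397628
Y,N,0.689131
Y,P,-0.204515
Y,Q,-0.824128
Y,R,0.598079
Y,S,0.592926
Y,T,-0.575617
Y,V,0.057473
Y,W,0.573218
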