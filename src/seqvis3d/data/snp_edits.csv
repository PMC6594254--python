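mark,mirna,rs,position,ref,alt,cancer_association
D1,hsa-mir-146a,rs2910164,50,A,G,gastric cancer
D2,hsa-mir-149,rs71428439,83,A,G,chronic lymphocytic leukemia
D3,hsa-mir-196a-2,rs11614913,78,C,T,breast cancer
D4,hsa-mir-608,rs4919510,37,C,G,breast cancer
D5,hsa-mir-612,rs12803915,51,G,A,B-cell acute lymphoblastic leukemia
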