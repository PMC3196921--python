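analysis,drug,outcome,or,ci_low,ci_high,placebo_rate_pct,prob,effect_size
classical,alendronate,nonvertebral,0.80,0.68,0.95,11.1,,
classical,alendronate,vertebral,0.51,0.40,0.63,6.7,,
classical,alendronate,hip,0.62,0.40,0.96,1.1,,
classical,alendronate,wrist,0.44,0.30,0.67,3.0,,
classical,denosumab,nonvertebral,0.80,0.67,0.96,7.5,,
classical,denosumab,vertebral,0.31,0.24,0.40,7.2,,
classical,denosumab,hip,0.60,0.37,0.98,1.1,,
classical,etidronate,nonvertebral,0.64,0.31,1.32,11.5,,
classical,etidronate,vertebral,0.59,0.32,1.10,9.7,,
classical,etidronate,hip,0.60,0.14,2.66,2.1,,
classical,etidronate,wrist,1.19,0.37,3.80,2.2,,
classical,ibandronate,nonvertebral,0.88,0.71,1.10,7.5,,
classical,ibandronate,vertebral,0.49,0.32,0.73,7.5,,
classical,raloxifene,nonvertebral,0.91,0.77,1.07,9.3,,
classical,raloxifene,vertebral,0.63,0.50,0.78,10.1,,
classical,raloxifene,hip,1.12,0.64,1.95,0.7,,
classical,raloxifene,wrist,0.88,0.67,1.15,3.3,,
classical,risedronate,nonvertebral,0.79,0.69,0.89,10.1,,
classical,risedronate,vertebral,0.59,0.47,0.75,13.3,,
classical,risedronate,hip,0.74,0.58,0.94,2.8,,
classical,risedronate,wrist,0.71,0.56,0.89,3.4,,
classical,strontium,nonvertebral,0.85,0.74,0.98,14.7,,
classical,strontium,vertebral,0.58,0.50,0.67,21.7,,
classical,strontium,wrist,1.59,1.12,2.27,3.2,,
classical,teriparatide,nonvertebral,0.62,0.40,0.97,9.7,,
classical,teriparatide,vertebral,0.31,0.19,0.52,14.3,,
classical,teriparatide,hip,0.50,0.09,2.75,0.7,,
classical,teriparatide,wrist,0.50,0.09,2.75,2.4,,
classical,zoledronic,nonvertebral,0.74,0.63,0.86,10.0,,
classical,zoledronic,vertebral,0.28,0.22,0.35,10.9,,
classical,all_drugs,nonvertebral,0.81,0.77,0.86,10.5,,
classical,all_drugs,vertebral,0.49,0.41,0.58,11.0,,
classical,all_drugs,hip,0.73,0.63,0.84,1.9,,
classical,all_drugs,wrist,0.82,0.71,0.94,3.1,,
bayesian,alendronate,nonvertebral,0.81,0.66,0.96,,0.01,16.1
bayesian,alendronate,vertebral,0.51,0.37,0.68,,<0.01,25.3
bayesian,alendronate,hip,0.59,0.29,0.99,,0.10,9.49
bayesian,alendronate,wrist,0.93,0.30,2.64,,0.10,1.80
bayesian,denosumab,nonvertebral,0.80,0.60,1.06,,0.03,10.7
bayesian,denosumab,vertebral,0.31,0.21,0.44,,0.20,53.6
bayesian,denosumab,hip,0.67,0.24,1.47,,0.12,4.76
bayesian,etidronate,nonvertebral,0.64,0.31,1.27,,0.42,6.4
bayesian,etidronate,vertebral,0.61,0.29,1.08,,0.01,8.3
bayesian,etidronate,hip,1.02,0.12,3.91,,0.19,1.01
bayesian,etidronate,wrist,2.42,0.25,10.54,,0.06,0.16
bayesian,ibandronate,nonvertebral,0.90,0.69,1.16,,<0.01,9.3
bayesian,ibandronate,vertebral,0.50,0.29,0.78,,0.01,16.1
bayesian,raloxifene,nonvertebral,0.91,0.69,1.20,,<0.01,8.4
bayesian,raloxifene,vertebral,0.63,0.43,0.90,,0.00,13.4
bayesian,raloxifene,hip,1.29,0.45,2.88,,0.01,1.25
bayesian,raloxifene,wrist,1.76,0.09,8.22,,0.15,0.27
bayesian,risedronate,nonvertebral,0.77,0.60,0.91,,0.04,16.4
bayesian,risedronate,vertebral,0.60,0.45,0.79,,0.00,19.3
bayesian,risedronate,hip,0.78,0.44,1.32,,0.01,5.71
bayesian,risedronate,wrist,0.91,0.13,3.27,,0.22,1.37
bayesian,strontium,nonvertebral,0.86,0.69,1.07,,<0.01,12.0
bayesian,strontium,vertebral,0.59,0.45,0.76,,<0.01,21.8
bayesian,strontium,hip,0.98,0.39,2.01,,0.01,2.47
bayesian,strontium,wrist,3.25,0.17,14.89,,0.06,0.08
bayesian,teriparatide,nonvertebral,0.62,0.38,1.02,,0.41,9.9
bayesian,teriparatide,vertebral,0.32,0.17,0.57,,0.30,29.8
bayesian,teriparatide,hip,0.71,0.04,2.90,,0.44,1.93
bayesian,teriparatide,wrist,1.23,0.05,5.64,,0.41,0.57
bayesian,zoledronic,nonvertebral,0.74,0.56,0.97,,0.08,12.9
bayesian,zoledronic,vertebral,0.28,0.19,0.40,,0.40,66.2
bayesian,zoledronic,hip,0.65,0.25,1.34,,0.11,5.53
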