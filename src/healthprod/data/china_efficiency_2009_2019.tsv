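unit	2009	2010	2011	2012	2013	2014	2015	2016	2017	2018	2019	max	min	mean	region
BeiJing	1.017	1.027	1.026	1.012	1.009	1.008	1.000	1.012	1.005	0.752	0.728	1.027	0.728	0.963	Eastern
TianJin	0.696	0.707	0.695	0.758	0.750	0.787	1.004	1.003	1.014	1.010	1.022	1.022	0.695	0.859	Eastern
HeBei	0.744	0.763	0.779	0.846	0.831	0.899	1.000	0.889	0.849	0.835	0.838	1.000	0.744	0.843	Eastern
GuangDong	1.019	1.030	1.034	1.024	1.027	1.027	1.037	1.037	1.036	1.032	1.031	1.037	1.019	1.030	Eastern
HaiNan	1.074	1.114	1.107	1.092	1.066	1.081	1.080	1.099	1.097	1.093	1.090	1.114	1.066	1.090	Eastern
ShangHai	0.655	0.816	0.747	0.787	0.758	0.820	0.872	1.004	0.904	0.830	0.765	1.004	0.655	0.814	Eastern
JiangSu	0.687	0.708	0.708	0.743	0.730	0.780	0.789	0.778	0.773	0.804	0.845	0.845	0.687	0.758	Eastern
ZheJiang	0.748	0.768	0.781	0.803	0.790	0.804	0.812	0.807	0.804	0.804	0.797	0.812	0.748	0.793	Eastern
FuJian	0.822	1.012	1.006	0.943	0.807	0.833	0.903	0.876	0.893	0.893	0.978	1.012	0.807	0.906	Eastern
ShanDong	0.706	0.717	0.705	0.710	0.734	0.724	0.738	0.727	0.715	0.725	0.723	0.738	0.705	0.720	Eastern
ShanXi	0.735	0.846	0.780	0.789	0.801	0.788	0.887	0.868	0.879	0.892	0.819	0.892	0.735	0.826	Middle
AnHui	1.002	1.008	1.008	0.975	1.008	1.004	1.002	1.002	1.003	1.008	1.013	1.013	0.975	1.003	Middle
JiangXi	1.073	1.032	1.044	1.028	1.024	1.025	1.020	1.023	1.011	1.008	1.004	1.073	1.004	1.027	Middle
HeNan	0.808	0.853	0.846	0.845	0.876	0.832	0.862	0.878	1.003	1.007	0.807	1.007	0.807	0.874	Middle
HuBei	0.761	0.824	0.830	0.805	0.804	0.758	0.798	0.760	0.753	0.763	0.783	0.830	0.753	0.785	Middle
HuNan	0.730	0.751	0.747	0.758	0.761	0.755	0.768	0.752	0.757	0.765	0.743	0.768	0.730	0.753	Middle
GuangXi	0.866	1.001	0.891	0.798	0.804	0.784	0.810	0.809	0.806	0.820	0.810	1.001	0.784	0.836	Western
ChongQing	1.005	0.822	0.838	0.825	0.872	0.812	0.830	0.790	0.780	0.760	0.751	1.005	0.751	0.826	Western
SiChuan	0.745	0.740	0.741	0.741	0.815	0.740	0.776	0.754	0.761	0.766	0.763	0.815	0.740	0.758	Western
GuiZhou	1.028	1.029	1.025	1.007	1.010	0.865	0.875	0.838	0.788	0.771	0.761	1.029	0.761	0.909	Western
YunNan	0.758	0.758	0.748	1.002	0.770	0.777	0.784	0.768	0.773	0.785	0.764	1.002	0.748	0.790	Western
XiZang	1.132	1.120	1.143	1.161	1.185	1.189	1.193	1.193	1.190	1.170	1.160	1.193	1.120	1.167	Western
ShaanXi	0.752	0.767	0.786	0.791	0.779	0.765	0.773	0.762	0.757	0.748	0.761	0.791	0.748	0.767	Western
GanSu	0.775	0.786	0.857	0.857	0.877	0.838	0.888	0.855	0.845	0.827	0.787	0.888	0.775	0.836	Western
QingHai	0.821	1.002	0.797	1.001	0.752	0.772	0.782	0.793	0.777	0.780	0.785	1.002	0.752	0.824	Western
NingXia	1.021	1.007	1.016	1.022	1.028	1.027	1.023	1.016	1.012	0.806	0.821	1.028	0.806	0.982	Western
XinJiang	0.697	0.676	0.731	0.741	0.713	0.722	0.749	0.812	0.833	0.860	1.001	1.001	0.676	0.776	Western
NeiMengGu	0.742	0.785	0.790	0.785	0.771	0.770	0.812	0.802	0.789	0.771	0.799	0.812	0.742	0.783	Western
LiaoNing	0.782	0.693	0.715	0.735	0.742	0.752	0.780	0.753	0.755	0.744	0.762	0.782	0.693	0.747	Northeastern
JiLin	1.007	0.749	0.808	0.892	0.959	0.794	0.910	0.838	0.815	0.796	0.798	1.007	0.749	0.852	Northeastern
HeiLongJiang	0.802	1.008	0.801	0.786	0.771	0.778	0.832	0.825	0.816	0.851	0.855	1.008	0.771	0.830	Northeastern
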